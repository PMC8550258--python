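"""Synthetic datasets with the structure of a perinatal protein study.

The real study data (albumin and AAG concentrations from pregnant and
postpartum women living with HIV) are access-restricted, so every stage of
the pipeline is exercised on generated data that reproduces the study's
published structure: cohort sizes, visit windows, the samples-per-subject
profile (most subjects contribute at most two samples), the reported
trajectory anchors, the reported error families, and rare implausibly high
albumin values (> 60 g/L) that the analysis excludes.

Each preset encodes a "true" mean curve through the published anchor values:

* albumin / pregnancy — linear through (20 wk, 34.3 g/L) and (37 wk, 33.4 g/L);
  essentially flat across gestation.
* albumin / postpartum — exponential saturation
  ``m(t) = 42.3 - 10.7 * exp(-k t)`` rising from 31.6 g/L at delivery to a
  42.3 g/L plateau, with k chosen so that m(3) = 38.3 g/L.
* AAG / pregnancy — linear through (24 wk, 53.6 mg/dL) and (37 wk, 44.9 mg/dL).
* AAG / postpartum — linear through (2 wk, 120.4 mg/dL) and (12 wk, 74.7 mg/dL).

Noise shapes that the source analysis does not print numerically (mixture
weights/offsets, the skew parameter, AAG dispersions) are declared defaults
and carry a ``not_from_source: True`` provenance flag in the preset metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._exceptions import DesignError, DomainError, ParameterError
from .distributions import (
    DistributionSpec,
    Family,
    mixture2_spec,
    normal_spec,
    sample as dist_sample,
    two_piece_mean_offset,
    two_piece_spec,
)
from .trajectory import ObservationSet

__all__ = [
    "TrajectoryPreset",
    "StudyDesign",
    "get_preset",
    "default_design",
    "preset_mean",
    "preset_noise_defaults",
    "generate_dataset",
    "PRESET_NAMES",
]

# exponential-saturation rate for the postpartum albumin rise:
# m(3) = 42.3 - 10.7*exp(-3k) = 38.3  =>  k = ln(10.7/4)/3
_POSTPARTUM_K = math.log(10.7 / 4.0) / 3.0


@dataclass(frozen=True)
class TrajectoryPreset:
    """True mean curve + noise model used by the generator."""

    analyte: str
    period: str
    domain: Tuple[float, float]
    mean_kind: str                 # "linear" | "exp_saturation"
    mean_params: Tuple[float, ...]  # linear: (t0, v0, t1, v1); exp: (plateau, drop, k)
    family: Family
    noise: Dict[str, object]
    metadata: Dict[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class StudyDesign:
    """Visit structure of one synthetic cohort.

    ``visit_windows`` is a sequence of ``(lo, hi, weight)`` triples; each
    sample's time is drawn uniformly within a weight-chosen window (a
    degenerate window such as ``(0, 0)`` pins samples to delivery).
    ``samples_per_subject`` maps a per-subject sample count to its
    probability.
    """

    n_subjects: int
    visit_windows: Tuple[Tuple[float, float, float], ...]
    samples_per_subject: Dict[int, float]
    outlier_count: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise DesignError("n_subjects must be >= 1")
        if not self.visit_windows:
            raise DesignError("at least one visit window is required")
        for lo, hi, w in self.visit_windows:
            if hi < lo or w < 0:
                raise DesignError(f"infeasible visit window ({lo}, {hi}, {w})")
        if sum(w for _, _, w in self.visit_windows) <= 0:
            raise DesignError("visit window weights must not all be zero")
        if any(c < 1 for c in self.samples_per_subject):
            raise DesignError("per-subject sample counts must be >= 1")
        total = sum(self.samples_per_subject.values())
        if abs(total - 1.0) > 1e-9:
            raise DesignError("samples_per_subject probabilities must sum to 1")
        if self.outlier_count < 0:
            raise DesignError("outlier_count must be >= 0")


_NOT_FROM_SOURCE = {"not_from_source": True}

_PRESETS: Dict[Tuple[str, str], TrajectoryPreset] = {
    ("albumin", "pregnancy"): TrajectoryPreset(
        analyte="albumin", period="pregnancy", domain=(20.0, 42.0),
        mean_kind="linear", mean_params=(20.0, 34.3, 37.0, 33.4),
        family=Family.MIXTURE2,
        noise={"weight_1": 0.8, "offset_1": 0.9, "offset_2": -3.6,
               "scale_1": 2.5, "scale_2": 5.0},
        metadata={"noise_shape": dict(_NOT_FROM_SOURCE)},
    ),
    ("albumin", "postpartum"): TrajectoryPreset(
        analyte="albumin", period="postpartum", domain=(0.0, 46.0),
        mean_kind="exp_saturation", mean_params=(42.3, 10.7, _POSTPARTUM_K),
        family=Family.TWO_PIECE_SKEW,
        noise={"skew": 0.8, "scale_low": 4.86, "scale_high": 3.64,
               "breakpoint": 0.5},
        metadata={"skew": dict(_NOT_FROM_SOURCE)},
    ),
    ("AAG", "pregnancy"): TrajectoryPreset(
        analyte="AAG", period="pregnancy", domain=(24.0, 38.0),
        mean_kind="linear", mean_params=(24.0, 53.6, 37.0, 44.9),
        family=Family.NORMAL,
        noise={"scale": 15.0},
        metadata={"scale": dict(_NOT_FROM_SOURCE)},
    ),
    ("AAG", "postpartum"): TrajectoryPreset(
        analyte="AAG", period="postpartum", domain=(2.0, 13.0),
        mean_kind="linear", mean_params=(2.0, 120.4, 12.0, 74.7),
        family=Family.NORMAL,
        noise={"scale": 25.0},
        metadata={"scale": dict(_NOT_FROM_SOURCE)},
    ),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def get_preset(analyte: str, period: str) -> TrajectoryPreset:
    try:
        return _PRESETS[(analyte, period)]
    except KeyError:
        raise ParameterError(
            f"no preset for analyte={analyte!r}, period={period!r}; "
            f"available: {PRESET_NAMES}") from None


def default_design(analyte: str, period: str,
                   outlier_count: Optional[int] = None) -> StudyDesign:
    """Cohort structure matching the published study sizes."""
    get_preset(analyte, period)  # validates the pair
    if (analyte, period) == ("albumin", "pregnancy"):
        d = StudyDesign(
            n_subjects=380,
            visit_windows=((20.0, 26.0, 0.40), (30.0, 38.0, 0.45), (37.0, 42.0, 0.15)),
            samples_per_subject={1: 0.25, 2: 0.45, 3: 0.15, 4: 0.10, 5: 0.05},
            outlier_count=1 if outlier_count is None else outlier_count)
    elif (analyte, period) == ("albumin", "postpartum"):
        d = StudyDesign(
            n_subjects=354,
            visit_windows=((0.0, 0.0, 0.12), (2.0, 24.0, 0.78), (24.0, 46.0, 0.10)),
            samples_per_subject={1: 0.30, 2: 0.38, 3: 0.17, 4: 0.10, 5: 0.05},
            outlier_count=1 if outlier_count is None else outlier_count)
    elif (analyte, period) == ("AAG", "pregnancy"):
        d = StudyDesign(
            n_subjects=31, visit_windows=((24.0, 38.0, 1.0),),
            samples_per_subject={1: 0.87, 2: 0.13},
            outlier_count=0 if outlier_count is None else outlier_count)
    else:
        d = StudyDesign(
            n_subjects=30, visit_windows=((2.0, 13.0, 1.0),),
            samples_per_subject={1: 0.93, 2: 0.07},
            outlier_count=0 if outlier_count is None else outlier_count)
    return d


def preset_mean(preset: TrajectoryPreset, t) -> np.ndarray:
    """True mean concentration of the preset at time(s) ``t`` (weeks)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    lo, hi = preset.domain
    if np.any(t_arr < lo) or np.any(t_arr > hi):
        raise DomainError(f"time outside preset domain [{lo}, {hi}]")
    if preset.mean_kind == "linear":
        t0, v0, t1, v1 = preset.mean_params
        out = v0 + (v1 - v0) * (t_arr - t0) / (t1 - t0)
    else:
        plateau, drop, k = preset.mean_params
        out = plateau - drop * np.exp(-k * t_arr)
    return out if np.ndim(t) else float(out[0])


def preset_noise_defaults(preset: TrajectoryPreset) -> Dict[str, object]:
    """The preset's noise parameters plus provenance flags.

    Values the source analysis does not print (mixture shape, skew, AAG
    dispersions) are declared defaults flagged ``not_from_source``.
    """
    return {"family": preset.family.value, "params": dict(preset.noise),
            "provenance": dict(preset.metadata)}


def _noise_spec_at(preset: TrajectoryPreset, m: float, t: float) -> DistributionSpec:
    """Family spec at time t, centred (in arithmetic mean) on m."""
    nz = preset.noise
    if preset.family is Family.NORMAL:
        return normal_spec(m, float(nz["scale"]))
    if preset.family is Family.MIXTURE2:
        return mixture2_spec(m, float(nz["weight_1"]), float(nz["offset_1"]),
                             float(nz["offset_2"]), float(nz["scale_1"]),
                             float(nz["scale_2"]))
    s = float(nz["scale_low"]) if t <= float(nz["breakpoint"]) else float(nz["scale_high"])
    nu = float(nz["skew"])
    mode = m - two_piece_mean_offset(s, nu)  # centre the arithmetic mean on m
    return two_piece_spec(mode, s, nu)


def generate_dataset(design: StudyDesign, preset: TrajectoryPreset,
                     seed: int) -> ObservationSet:
    """Draw one synthetic cohort; fully reproducible given ``seed``.

    Per subject, a sample count is drawn from the design's profile; each
    sample's visit time comes from a weight-chosen window and its
    concentration from the preset's family centred on the preset mean.
    Non-positive draws (possible only in far tails) are redrawn.  Finally the
    configured number of implausible outliers (> 60 g/L) is injected by
    overwriting randomly chosen records.
    """
    lo, hi = preset.domain
    for wlo, whi, w in design.visit_windows:
        if w > 0 and (wlo < lo or whi > hi):
            raise DesignError(
                f"visit window ({wlo}, {whi}) outside preset domain [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    counts = np.array(sorted(design.samples_per_subject))
    probs = np.array([design.samples_per_subject[c] for c in counts], dtype=float)
    win = np.asarray(design.visit_windows, dtype=float)
    wweights = win[:, 2] / win[:, 2].sum()

    rows = []
    for i in range(design.n_subjects):
        sid = f"S{i + 1:04d}"
        c = int(rng.choice(counts, p=probs))
        for _ in range(c):
            k = int(rng.choice(len(win), p=wweights))
            t = float(rng.uniform(win[k, 0], win[k, 1])) if win[k, 1] > win[k, 0] \
                else float(win[k, 0])
            m = float(preset_mean(preset, t))
            spec = _noise_spec_at(preset, m, t)
            y = float(dist_sample(spec, 1, rng)[0])
            while y <= 0:  # far-tail guard; redraw keeps the stream seeded
                y = float(dist_sample(spec, 1, rng)[0])
            rows.append((sid, preset.analyte, preset.period, t, y))

    df = pd.DataFrame(rows, columns=list(ObservationSet.REQUIRED_COLUMNS))
    if design.outlier_count > 0:
        if design.outlier_count > len(df):
            raise DesignError("more outliers requested than records generated")
        idx = rng.choice(len(df), size=design.outlier_count, replace=False)
        df.loc[df.index[idx], "concentration"] = rng.uniform(
            61.0, 75.0, size=design.outlier_count)
    return ObservationSet(df)
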