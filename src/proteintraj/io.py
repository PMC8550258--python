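"""Configuration, readers/writers and the end-to-end pipeline runner.

Artifacts are plain text: CSV for tabular outputs (comma-separated, UTF-8,
header row, decimal point) and schema-versioned JSON for models and function
bundles.  All randomness flows from the single configuration seed, which is
embedded in every artifact's provenance block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from ._exceptions import SchemaError, ValidationError
from .computational import (
    ComputationalFunctionSet,
    build_function_set,
    export_function_bundle,
)
from .distributions import Family
from .splines import BasisSpec
from .synthetic import default_design, generate_dataset, get_preset
from .trajectory import (
    DEFAULT_PERCENTILES,
    DistributionalTrajectory,
    FittedTrajectoryModel,
    ModelSpec,
    ObservationSet,
    VarianceSpec,
    coverage_table,
    exclude_outliers,
    fit_trajectory_model,
    quantile_curves,
    select_model,
)

__all__ = [
    "PipelineConfig",
    "read_observations",
    "write_observations",
    "model_to_dict",
    "model_from_dict",
    "run_pipeline",
]

logger = logging.getLogger("proteintraj.pipeline")

MODEL_SCHEMA_VERSION = "1"


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, with study defaults."""

    analyte: str = "albumin"
    period: str = "pregnancy"
    families: Tuple[str, ...] = ("normal", "mixture2", "two_piece_skew")
    variance_models: Tuple[str, ...] = ("constant", "piecewise_constant")
    variance_breakpoint: float = 0.5
    percentiles: Tuple[float, ...] = DEFAULT_PERCENTILES
    r2_threshold: float = 0.995
    delta: float = 2.034
    outlier_threshold: Optional[float] = 60.0  # g/L; albumin only
    seed: int = 0
    n_interior_knots: int = 20
    penalty_order: int = 2
    gaic_k: float = 2.0
    grid_points: int = 101
    input_path: Optional[str] = None  # None -> simulate from the preset

    def validate(self) -> None:
        from .trajectory import ANALYTES, PERIODS
        if self.analyte not in ANALYTES:
            raise ValidationError(f"unknown analyte {self.analyte!r}")
        if self.period not in PERIODS:
            raise ValidationError(f"unknown period {self.period!r}")
        if len(self.families) == 0:
            raise ValidationError("candidate family list must not be empty")
        for f in self.families:
            try:
                Family(f)
            except ValueError:
                raise ValidationError(f"unknown family {f!r}") from None
        if len(self.variance_models) == 0:
            raise ValidationError("variance-model candidate list must not be empty")
        for v in self.variance_models:
            if v not in ("constant", "piecewise_constant", "smooth_in_time"):
                raise ValidationError(f"unknown variance model {v!r}")
        p = np.asarray(self.percentiles, dtype=float)
        if len(p) == 0 or np.any(p <= 0) or np.any(p >= 100) or np.any(np.diff(p) <= 0):
            raise ValidationError(
                "percentiles must be strictly increasing within (0, 100)")
        if not (0 < self.r2_threshold < 1):
            raise ValidationError("r2_threshold must lie in (0, 1)")
        if self.outlier_threshold is not None and self.outlier_threshold <= 0:
            raise ValidationError("outlier_threshold must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValidationError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("families", "variance_models", "percentiles"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# observation CSV
# ---------------------------------------------------------------------------

def read_observations(path) -> ObservationSet:
    """Read an observation CSV, collecting row-level errors with line numbers."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ObservationSet.REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    errors: List[str] = []
    times = np.empty(len(df))
    concs = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            times[i] = float(row.time)
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric time {row.time!r}")
            times[i] = np.nan
        try:
            concs[i] = float(row.concentration)
        except (TypeError, ValueError):
            errors.append(
                f"line {line}: non-numeric concentration {row.concentration!r}")
            concs[i] = np.nan
        if np.isfinite(times[i]) and times[i] < 0:
            errors.append(f"line {line}: negative time {times[i]}")
        if np.isfinite(concs[i]) and concs[i] <= 0:
            errors.append(f"line {line}: non-positive concentration {concs[i]}")
    if errors:
        raise ValidationError(
            f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors))
    out = df.copy()
    out["time"] = times
    out["concentration"] = concs
    return ObservationSet(out[list(ObservationSet.REQUIRED_COLUMNS)])


def write_observations(data: ObservationSet, path) -> None:
    data.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fitted-model JSON round-trip
# ---------------------------------------------------------------------------

def model_to_dict(model: FittedTrajectoryModel, seed: Optional[int] = None) -> dict:
    est = model.estimator
    bs = est.basis_spec_
    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "analyte": model.analyte,
        "period": model.period,
        "n_obs": model.n_obs,
        "family": Family(est.family).value,
        "basis": {"domain_lo": bs.domain_lo, "domain_hi": bs.domain_hi,
                  "n_interior_knots": bs.n_interior_knots, "degree": bs.degree},
        "penalty_order": est.penalty_order,
        "lambda": est.lam_,
        "location_coefficients": [float(c) for c in est.location_coef_],
        "scale_params": dict(est.scale_params_),
        "shape_params": dict(est.shape_params_),
        "loglik": float(est.loglik_),
        "edf": float(est.edf_),
        "gaic": float(est.gaic_),
        "gaic_k": est.gaic_k,
        "converged": bool(est.converged_),
        "n_iter": int(est.n_iter_),
        "provenance": {} if seed is None else {"seed": int(seed)},
    }


def model_from_dict(doc: dict) -> FittedTrajectoryModel:
    """Rebuild a fitted model (for quantile/coverage use) from its JSON form."""
    for key in ("family", "basis", "location_coefficients", "scale_params",
                "shape_params", "loglik", "edf", "analyte", "period"):
        if key not in doc:
            raise SchemaError(f"model document is missing field '{key}'")
    b = doc["basis"]
    est = DistributionalTrajectory(
        family=doc["family"],
        variance=doc["scale_params"].get("kind", "constant"),
        n_interior_knots=int(b["n_interior_knots"]), degree=int(b["degree"]),
        penalty_order=int(doc.get("penalty_order", 2)),
        gaic_k=float(doc.get("gaic_k", 2.0)))
    est.basis_spec_ = BasisSpec(float(b["domain_lo"]), float(b["domain_hi"]),
                                int(b["n_interior_knots"]), int(b["degree"]))
    est.domain_ = (est.basis_spec_.domain_lo, est.basis_spec_.domain_hi)
    est.location_coef_ = np.asarray(doc["location_coefficients"], dtype=float)
    est.scale_params_ = dict(doc["scale_params"])
    est.shape_params_ = dict(doc["shape_params"])
    est.lam_ = float(doc.get("lambda", 0.0))
    est.loglik_ = float(doc["loglik"])
    est.edf_ = float(doc["edf"])
    est.gaic_ = float(doc.get("gaic", -2 * est.loglik_ + est.gaic_k * est.edf_))
    est.converged_ = bool(doc.get("converged", True))
    est.n_iter_ = int(doc.get("n_iter", 0))
    spec = ModelSpec(Family(doc["family"]),
                     VarianceSpec(est.scale_params_.get("kind", "constant"),
                                  float(est.scale_params_.get("breakpoint", 0.5))),
                     n_interior_knots=int(b["n_interior_knots"]),
                     degree=int(b["degree"]),
                     penalty_order=int(doc.get("penalty_order", 2)))
    return FittedTrajectoryModel(est, str(doc["analyte"]), str(doc["period"]),
                                 int(doc.get("n_obs", 0)), spec)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _candidate_specs(config: PipelineConfig, times: np.ndarray) -> List[ModelSpec]:
    specs = []
    t_lo, t_hi = float(times.min()), float(times.max())
    families = config.families
    variance_models = config.variance_models
    if config.analyte == "AAG":
        # too few AAG samples to discriminate error families or variance
        # structure; model the central tendency with a Gaussian smoother
        families = ("normal",)
        variance_models = ("constant",)
        logger.info("stage candidates: AAG analysis restricted to a Gaussian "
                    "constant-variance smoother (sparse data)")
    for fam in families:
        fam_t = Family(fam)
        for var in variance_models:
            if fam_t is Family.MIXTURE2 and var != "constant":
                continue  # the mixture carries its own component scales
            if var == "piecewise_constant" and not (
                    t_lo < config.variance_breakpoint < t_hi):
                continue  # breakpoint outside the observed range
            specs.append(ModelSpec(
                fam_t, VarianceSpec(var, config.variance_breakpoint),
                n_interior_knots=config.n_interior_knots,
                penalty_order=config.penalty_order, gaic_k=config.gaic_k))
    if not specs:
        raise ValidationError("no feasible candidate models for this configuration")
    return specs


def run_pipeline(config: PipelineConfig, out_dir) -> Dict[str, Path]:
    """Simulate-or-load, filter, fit, select, validate, approximate, export.

    Returns a mapping of artifact names to paths: ``data``, ``model``,
    ``quantiles``, ``coverage``, ``bundle``, ``log``.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_pipeline_inner(config, out, log_path)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(config: PipelineConfig, out: Path,
                        log_path: Path) -> Dict[str, Path]:
    logger.info("config: %s", config)
    if config.input_path is not None:
        data = read_observations(config.input_path)
        data = data.subset(config.analyte, config.period)
        logger.info("stage load: %d records from %s", len(data), config.input_path)
    else:
        preset = get_preset(config.analyte, config.period)
        design = default_design(config.analyte, config.period)
        data = generate_dataset(design, preset, config.seed)
        logger.info("stage simulate: %d records, seed %d", len(data), config.seed)
    data_path = out / "observations.csv"
    write_observations(data, data_path)

    if config.analyte == "albumin" and config.outlier_threshold is not None:
        data, n_removed = exclude_outliers(data, config.outlier_threshold)
        logger.info("stage filter: removed %d record(s) above %.1f g/L",
                    n_removed, config.outlier_threshold)

    specs = _candidate_specs(config, data.times)
    candidates = []
    for spec in specs:
        m = fit_trajectory_model(data, spec, random_state=config.seed)
        logger.info("stage fit: family=%s variance=%s loglik=%.3f edf=%.2f "
                    "gaic=%.3f converged=%s", spec.family.value,
                    spec.variance.kind, m.loglik, m.edf, m.aic, m.converged)
        candidates.append(m)

    selected = select_model(candidates, delta=config.delta)
    logger.info("stage select: family=%s variance=%s (delta=%.3f)",
                selected.spec.family.value, selected.spec.variance.kind,
                config.delta)

    model_path = out / "model.json"
    model_path.write_text(
        json.dumps(model_to_dict(selected, seed=config.seed), indent=2),
        encoding="utf-8")

    lo, hi = selected.domain
    grid = np.linspace(lo, hi, config.grid_points)
    qc = quantile_curves(selected, config.percentiles, grid)
    quantiles_path = out / "quantiles.csv"
    qc.to_frame().to_csv(quantiles_path, index=False)
    logger.info("stage quantiles: %d percentiles on %d grid points",
                len(config.percentiles), config.grid_points)

    cov = coverage_table(selected, data, config.percentiles)
    coverage_path = out / "coverage.csv"
    cov.to_frame().to_csv(coverage_path, index=False)
    logger.info("stage coverage: observed %% below = %s",
                np.round(cov.observed_percent, 2).tolist())

    fs = build_function_set(
        selected, config.analyte, config.period,
        r2_threshold=config.r2_threshold,
        provenance={"seed": config.seed,
                    "family": selected.spec.family.value,
                    "variance": selected.spec.variance.kind})
    bundle_path = out / "bundle.json"
    bundle_path.write_text(json.dumps(export_function_bundle(fs), indent=2),
                           encoding="utf-8")
    logger.info("stage approximate: degree %d polynomial, R^2 = %.6f",
                fs.mean_poly.degree, fs.mean_poly.r_squared)

    return {"data": data_path, "model": model_path, "quantiles": quantiles_path,
            "coverage": coverage_path, "bundle": bundle_path, "log": log_path}
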