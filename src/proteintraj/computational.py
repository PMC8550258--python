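"""Exportable computational functions for PBPK virtual populations.

The end product of a trajectory fit is a small set of parametric functions a
PBPK platform can evaluate without the nonparametric machinery:

1. a *mean function* — a least-squares polynomial approximating the fitted
   arithmetic-mean curve, the degree increased from 1 until the coefficient
   of determination against the nonparametric curve exceeds a threshold
   (0.995 by default);
2. a *quantile function* — the family quantile around that mean, using the
   fitted scale/shape (mean -> location uses the family's closed-form
   inverse: identity for the normal and the constrained mixture, the
   mean-mode offset for the two-piece normal);
3. a *stochastic sampler* — seeded draws of (time, concentration) pairs for
   virtual-population generation.

Function sets round-trip through a schema-validated JSON document so they
can be archived and re-imported exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import distributions as dist
from ._exceptions import ApproximationError, DomainError, ParameterError, SchemaError
from .distributions import (
    Family,
    mixture2_spec,
    normal_spec,
    two_piece_mean_offset,
    two_piece_spec,
)

__all__ = [
    "PolynomialApproximation",
    "ComputationalFunctionSet",
    "approximate_mean_polynomial",
    "mean_function_eval",
    "quantile_function_eval",
    "sample_virtual_population",
    "export_function_bundle",
    "import_function_bundle",
    "build_function_set",
]

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class PolynomialApproximation:
    """Polynomial (ascending coefficients) valid on a closed time domain."""

    coefficients: tuple
    degree: int
    r_squared: float
    domain: tuple

    def __call__(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.domain
        if np.any(t_arr < lo) or np.any(t_arr > hi):
            raise DomainError(
                f"evaluation time outside polynomial domain [{lo}, {hi}]")
        out = np.polynomial.polynomial.polyval(t_arr, np.asarray(self.coefficients))
        return out if np.ndim(t) else float(out[0])


def approximate_mean_polynomial(curve, domain, r2_threshold: float = 0.995,
                                grid_step: float = 0.1,
                                max_degree: int = 10) -> PolynomialApproximation:
    """Lowest-degree polynomial with R^2 above threshold against ``curve``.

    ``curve`` is any callable over ``domain = (lo, hi)``.  Degrees 1, 2, ...
    are fit by least squares on a ``grid_step``-spaced grid; the first degree
    whose R^2 (computed on that grid against the curve's values) exceeds
    ``r2_threshold`` is returned.
    """
    if not (0.0 < r2_threshold < 1.0):
        raise ParameterError("r2_threshold must lie in (0, 1)")
    if grid_step <= 0:
        raise ParameterError("grid_step must be > 0")
    lo, hi = float(domain[0]), float(domain[1])
    if not lo < hi:
        raise ParameterError("domain must satisfy lo < hi")
    grid = np.append(np.arange(lo, hi, grid_step), hi)
    target = np.asarray(curve(grid), dtype=float)
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    best_r2 = -np.inf
    for degree in range(1, max_degree + 1):
        coefs = np.polynomial.polynomial.polyfit(grid, target, degree)
        fitted = np.polynomial.polynomial.polyval(grid, coefs)
        ss_res = float(np.sum((target - fitted) ** 2))
        r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
        best_r2 = max(best_r2, r2)
        if r2 > r2_threshold:
            return PolynomialApproximation(tuple(float(c) for c in coefs),
                                           degree, float(r2), (lo, hi))
    raise ApproximationError(
        f"no polynomial of degree <= {max_degree} reached R^2 > {r2_threshold} "
        f"(best {best_r2:.6f})")


@dataclass(frozen=True)
class ComputationalFunctionSet:
    """Mean polynomial + variance model + family shape for one analyte/period."""

    analyte: str
    period: str
    mean_poly: PolynomialApproximation
    family: Family
    variance: Dict[str, float]   # {"kind": ..., plus scale entries}
    shape: Dict[str, float]      # family shape block (empty for normal)
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def domain(self) -> tuple:
        return self.mean_poly.domain


def build_function_set(model, analyte: str, period: str,
                       r2_threshold: float = 0.995, grid_step: float = 0.1,
                       provenance: Optional[dict] = None) -> ComputationalFunctionSet:
    """Assemble a function set from a fitted trajectory model."""
    est = getattr(model, "estimator", model)
    lo, hi = est.domain_
    poly = approximate_mean_polynomial(
        lambda tt: est.predict(tt), (lo, hi),
        r2_threshold=r2_threshold, grid_step=grid_step)
    fam = Family(est.family)
    variance = {k: v for k, v in est.scale_params_.items()}
    shape = dict(est.shape_params_)
    return ComputationalFunctionSet(analyte, period, poly, fam, variance, shape,
                                    dict(provenance or {}))


def _scale_at(fs: ComputationalFunctionSet, t: float) -> float:
    v = fs.variance
    kind = v.get("kind", "constant")
    if kind == "constant":
        return float(v["scale"])
    if kind == "piecewise_constant":
        return float(v["scale_low"]) if t <= float(v["breakpoint"]) \
            else float(v["scale_high"])
    return float(np.exp(float(v["a"]) + float(v["b"]) * t))


def local_spec(fs: ComputationalFunctionSet, t: float) -> dist.DistributionSpec:
    """Concentration distribution implied by the function set at time t."""
    m = float(fs.mean_poly(t))
    if fs.family is Family.NORMAL:
        return normal_spec(m, _scale_at(fs, t))
    if fs.family is Family.MIXTURE2:
        s = fs.shape
        return mixture2_spec(m, float(s["weight_1"]), float(s["offset_1"]),
                             float(s["offset_2"]), float(s["scale_1"]),
                             float(s["scale_2"]))
    sigma = _scale_at(fs, t)
    nu = float(fs.shape["skew"])
    mode = m - two_piece_mean_offset(sigma, nu)
    return two_piece_spec(mode, sigma, nu)


def mean_function_eval(fs: ComputationalFunctionSet, t) -> float:
    """Arithmetic-mean concentration at time ``t`` (closed domain)."""
    return fs.mean_poly(t)


def quantile_function_eval(fs: ComputationalFunctionSet, t: float,
                           percentile: float) -> float:
    """Concentration quantile at time ``t``; ``percentile`` in (0, 1)."""
    if not (0.0 < percentile < 1.0):
        raise ParameterError("percentile must lie strictly in (0, 1)")
    return float(dist.quantile(local_spec(fs, t), percentile))


def sample_virtual_population(fs: ComputationalFunctionSet, n: int,
                              time_sampler: Optional[dict] = None,
                              seed: int = 0) -> pd.DataFrame:
    """Seeded table of (time, concentration) rows for PBPK population input.

    ``time_sampler`` is ``{"kind": "uniform"}`` (default, over the bundle
    domain), ``{"kind": "fixed", "time": t0}`` or
    ``{"kind": "empirical", "times": [...]}`` (resampled with replacement).
    """
    if n < 1:
        raise ParameterError("population size must be >= 1")
    lo, hi = fs.domain
    if not lo < hi:
        raise DomainError("function-set domain is empty")
    rng = np.random.default_rng(seed)
    ts = time_sampler or {"kind": "uniform"}
    kind = ts.get("kind", "uniform")
    if kind == "uniform":
        times = rng.uniform(lo, hi, size=n)
    elif kind == "fixed":
        t0 = float(ts["time"])
        if not lo <= t0 <= hi:
            raise DomainError(f"fixed time {t0} outside domain [{lo}, {hi}]")
        times = np.full(n, t0)
    elif kind == "empirical":
        pool = np.asarray(ts["times"], dtype=float)
        if np.any(pool < lo) or np.any(pool > hi):
            raise DomainError("empirical time pool leaves the bundle domain")
        times = rng.choice(pool, size=n, replace=True)
    else:
        raise ParameterError(f"unknown time sampler kind {kind!r}")
    conc = np.empty(n)
    # draws stream from one generator so the whole table is seed-reproducible
    for i, t in enumerate(times):
        conc[i] = dist.sample(local_spec(fs, float(t)), 1, rng)[0]
    return pd.DataFrame({"time": times, "concentration": conc})


# ---------------------------------------------------------------------------
# JSON bundle round-trip
# ---------------------------------------------------------------------------

def export_function_bundle(fs: ComputationalFunctionSet) -> dict:
    """Serialize a function set to a schema-versioned JSON-compatible dict."""
    return {
        "schema_version": SCHEMA_VERSION,
        "analyte": fs.analyte,
        "period": fs.period,
        "mean_polynomial": {
            "coefficients": list(fs.mean_poly.coefficients),
            "degree": fs.mean_poly.degree,
            "r_squared": fs.mean_poly.r_squared,
            "domain": list(fs.mean_poly.domain),
        },
        "family": fs.family.value,
        "variance": dict(fs.variance),
        "shape": dict(fs.shape),
        "provenance": dict(fs.provenance),
    }


_REQUIRED = {
    "schema_version": str,
    "analyte": str,
    "period": str,
    "mean_polynomial": dict,
    "family": str,
    "variance": dict,
    "shape": dict,
}
_POLY_REQUIRED = {"coefficients": list, "degree": int, "r_squared": (int, float),
                  "domain": list}


def _require(doc: dict, spec: dict, prefix: str = "") -> None:
    for key, typ in spec.items():
        path = f"{prefix}{key}"
        if key not in doc:
            raise SchemaError(f"function bundle is missing required field '{path}'")
        if not isinstance(doc[key], typ):
            raise SchemaError(
                f"field '{path}' has type {type(doc[key]).__name__}, "
                f"expected {typ.__name__ if isinstance(typ, type) else typ}")


def import_function_bundle(doc) -> ComputationalFunctionSet:
    """Rebuild a function set from its JSON document (dict or JSON string)."""
    if isinstance(doc, str):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"bundle is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("function bundle must be a JSON object")
    _require(doc, _REQUIRED)
    if doc["schema_version"] != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version {doc['schema_version']!r}; "
            f"expected {SCHEMA_VERSION!r}")
    _require(doc["mean_polynomial"], _POLY_REQUIRED, prefix="mean_polynomial.")
    mp = doc["mean_polynomial"]
    if len(mp["domain"]) != 2:
        raise SchemaError("field 'mean_polynomial.domain' must have two entries")
    try:
        fam = Family(doc["family"])
    except ValueError:
        raise SchemaError(f"unknown family {doc['family']!r}") from None
    if "kind" not in doc["variance"]:
        raise SchemaError("field 'variance.kind' is missing")
    poly = PolynomialApproximation(
        tuple(float(c) for c in mp["coefficients"]), int(mp["degree"]),
        float(mp["r_squared"]), (float(mp["domain"][0]), float(mp["domain"][1])))
    return ComputationalFunctionSet(
        str(doc["analyte"]), str(doc["period"]), poly, fam,
        dict(doc["variance"]), dict(doc["shape"]), dict(doc.get("provenance", {})))
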