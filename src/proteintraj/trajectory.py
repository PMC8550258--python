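"""Location–scale(–shape) trajectory regression for plasma protein data.

The central estimator, :class:`DistributionalTrajectory`, models an analyte
concentration as

    y_i ~ F(location(t_i), scale(t_i), shape)

where the location follows a penalized B-spline in time, the scale is
constant, piecewise constant in time (split at a configurable breakpoint,
e.g. 0.5 weeks postpartum) or log-linear in time, and F is one of the three
error families in :mod:`proteintraj.distributions`.  Fitting alternates

  (a) a penalized weighted least-squares update of the location spline given
      the current scale/shape (and, for the mixture, the EM responsibilities),
  (b) maximum-likelihood updates of scale and shape given the location curve,

until the relative change in penalized log-likelihood falls below ``tol`` or
``max_iter`` is reached.  The smoothing weight lambda is selected once by
generalized AIC on a preliminary Gaussian fit and held fixed thereafter.
Observations are treated as independent; no within-subject correlation is
modelled.

Model comparison uses generalized AIC, ``-2*loglik + k*edf``, where edf is
the trace of the location smoother's hat matrix plus the number of free
scale/shape parameters.  A more complex candidate displaces a simpler one
only if its AIC advantage exceeds a configurable ``delta`` (default 2.034),
encoding the judgment that minute AIC differences do not justify extra
structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, RegressorMixin

from . import distributions as dist
from ._exceptions import (
    DomainError,
    FitFailureError,
    InsufficientDataError,
    ParameterError,
    ValidationError,
)
from .distributions import (
    DistributionSpec,
    Family,
    mixture2_spec,
    normal_spec,
    two_piece_mean_offset,
    two_piece_spec,
)
from .splines import (
    BasisSpec,
    PenaltySpec,
    build_basis,
    difference_matrix,
    fit_penalized_wls,
    select_lambda_gaic,
)

__all__ = [
    "ObservationSet",
    "VarianceSpec",
    "ModelSpec",
    "DistributionalTrajectory",
    "FittedTrajectoryModel",
    "QuantileCurveSet",
    "CoverageTable",
    "ResidualDiagnostics",
    "fit_trajectory_model",
    "gaic",
    "select_model",
    "quantile_curves",
    "coverage_table",
    "quantile_residual_diagnostics",
    "exclude_outliers",
]

ANALYTES = ("albumin", "AAG")
PERIODS = ("pregnancy", "postpartum")

_PREGNANCY_LO, _PREGNANCY_HI = 20.0, 43.0


# ---------------------------------------------------------------------------
# observation container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservationSet:
    """Longitudinal analyte concentrations with subject/time/period metadata.

    Concentrations are g/L for albumin and mg/dL for AAG.  Pregnancy times
    are weeks of gestational age and must lie in [20, 43] (study eligibility
    started at 20 weeks gestation); postpartum time 0 is the date of
    delivery.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED_COLUMNS = ("subject_id", "analyte", "period", "time", "concentration")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required column(s): {missing}")
        if len(df) == 0:
            return
        bad_analyte = set(df["analyte"].unique()) - set(ANALYTES)
        if bad_analyte:
            raise ValidationError(f"unknown analyte value(s): {sorted(bad_analyte)}")
        bad_period = set(df["period"].unique()) - set(PERIODS)
        if bad_period:
            raise ValidationError(f"unknown period value(s): {sorted(bad_period)}")
        if (df["concentration"] <= 0).any():
            raise ValidationError("concentrations must be strictly positive")
        if (df["time"] < 0).any():
            raise ValidationError("times must be non-negative (weeks)")
        preg = df[df["period"] == "pregnancy"]
        if len(preg) and ((preg["time"] < _PREGNANCY_LO) | (preg["time"] > _PREGNANCY_HI)).any():
            raise ValidationError(
                f"pregnancy times must lie in [{_PREGNANCY_LO}, {_PREGNANCY_HI}] weeks")

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, analyte: Optional[str] = None,
               period: Optional[str] = None) -> "ObservationSet":
        df = self.frame
        if analyte is not None:
            df = df[df["analyte"] == analyte]
        if period is not None:
            df = df[df["period"] == period]
        return ObservationSet(df.reset_index(drop=True))

    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return self.frame["concentration"].to_numpy(dtype=float)


def exclude_outliers(data: ObservationSet, threshold: float):
    """Drop records with concentration above ``threshold``; return (set, count).

    Mirrors the exclusion of implausibly high serum albumin values
    (> 60 g/L) before model fitting.
    """
    if threshold <= 0:
        raise ParameterError("outlier threshold must be > 0")
    keep = data.frame["concentration"] <= threshold
    removed = int((~keep).sum())
    return ObservationSet(data.frame[keep].reset_index(drop=True)), removed


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceSpec:
    """Scale model: constant, split at a time breakpoint, or log-linear."""

    kind: str = "constant"  # constant | piecewise_constant | smooth_in_time
    breakpoint: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "piecewise_constant", "smooth_in_time"):
            raise ParameterError(f"unknown variance model kind {self.kind!r}")

    @property
    def n_params(self) -> int:
        return {"constant": 1, "piecewise_constant": 2, "smooth_in_time": 2}[self.kind]


@dataclass(frozen=True)
class ModelSpec:
    """Family + smoother + variance model defining one candidate."""

    family: Family = Family.NORMAL
    variance: VarianceSpec = field(default_factory=VarianceSpec)
    n_interior_knots: int = 20
    degree: int = 3
    penalty_order: int = 2
    lam: Optional[float] = None
    gaic_k: float = 2.0

    def __post_init__(self) -> None:
        fam = Family(self.family)
        if fam is Family.MIXTURE2 and self.variance.kind != "constant":
            raise ParameterError(
                "the mixture family carries its own component scales; "
                "combine it with a constant variance model")


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class DistributionalTrajectory(BaseEstimator, RegressorMixin):
    """Penalized-spline distributional regression of concentration on time.

    Parameters
    ----------
    family : {"normal", "mixture2", "two_piece_skew"}
        Error family around the time-varying location.
    variance : {"constant", "piecewise_constant", "smooth_in_time"}
        Scale model.  ``piecewise_constant`` splits at ``variance_breakpoint``
        weeks; ``smooth_in_time`` makes log(scale) linear in time.
    variance_breakpoint : float
        Split point (weeks) for the piecewise scale, default 0.5.
    n_interior_knots, degree, penalty_order : int
        P-spline configuration for the location curve.
    lam : float or None
        Smoothing weight; ``None`` selects it by generalized AIC.
    gaic_k : float
        Per-edf penalty in the generalized AIC, default 2.
    max_iter, tol : iteration control for the alternating fit.
    n_restarts : int
        EM restarts for the mixture family (first from a residual-quantile
        split, the rest random), best penalized likelihood kept.
    random_state : int
        Seeds the EM restarts.

    Attributes
    ----------
    mean_ : callable mapping times to the fitted arithmetic-mean curve.
    location_coef_ : spline coefficients of the location curve.
    scale_params_, shape_params_ : fitted scale/shape blocks.
    loglik_, edf_, gaic_ : fit summaries.
    converged_, n_iter_, loglik_path_ : iteration diagnostics.
    domain_ : fitted time domain (no extrapolation outside it).
    """

    def __init__(self, family: str = "normal", variance: str = "constant",
                 variance_breakpoint: float = 0.5, n_interior_knots: int = 20,
                 degree: int = 3, penalty_order: int = 2,
                 lam: Optional[float] = None, gaic_k: float = 2.0,
                 max_iter: int = 500, tol: float = 1e-8,
                 n_restarts: int = 5, random_state: int = 0):
        self.family = family
        self.variance = variance
        self.variance_breakpoint = variance_breakpoint
        self.n_interior_knots = n_interior_knots
        self.degree = degree
        self.penalty_order = penalty_order
        self.lam = lam
        self.gaic_k = gaic_k
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _scale_at(self, t: np.ndarray, scale_params: dict) -> np.ndarray:
        kind = scale_params["kind"]
        if kind == "constant":
            return np.full_like(t, scale_params["scale"])
        if kind == "piecewise_constant":
            return np.where(t <= scale_params["breakpoint"],
                            scale_params["scale_low"], scale_params["scale_high"])
        return np.exp(scale_params["a"] + scale_params["b"] * t)

    def _update_scale(self, t, resid2, scale_params, floor):
        """ML scale update given side-weighted squared residuals."""
        kind = scale_params["kind"]
        out = dict(scale_params)
        if kind == "constant":
            out["scale"] = max(np.sqrt(np.mean(resid2)), floor)
        elif kind == "piecewise_constant":
            low = t <= scale_params["breakpoint"]
            if low.any():
                out["scale_low"] = max(np.sqrt(np.mean(resid2[low])), floor)
            if (~low).any():
                out["scale_high"] = max(np.sqrt(np.mean(resid2[~low])), floor)
        else:
            # log sigma = a + b t, Gaussian profile likelihood in (a, b)
            a0, b0 = scale_params["a"], scale_params["b"]

            def nll(params):
                a, b = params
                s2 = np.exp(2.0 * (a + b * t))
                return float(np.sum(np.log(s2) + resid2 / s2)) / 2.0

            from scipy.optimize import minimize
            res = minimize(nll, np.array([a0, b0]), method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
            out["a"], out["b"] = float(res.x[0]), float(res.x[1])
        return out

    def _local_spec(self, loc: float, scale: float, shape: dict) -> DistributionSpec:
        fam = Family(self.family)
        if fam is Family.NORMAL:
            return normal_spec(loc, scale)
        if fam is Family.TWO_PIECE_SKEW:
            # loc here is the mode; mean follows from the closed-form offset
            return two_piece_spec(loc, scale, shape["skew"])
        return mixture2_spec(loc, shape["weight_1"], shape["offset_1"],
                             shape["offset_2"], shape["scale_1"], shape["scale_2"])

    # -- likelihoods ------------------------------------------------------

    def _loglik(self, t, y, loc, scale_params, shape) -> float:
        fam = Family(self.family)
        s = self._scale_at(t, scale_params)
        if fam is Family.NORMAL:
            return float(np.sum(stats.norm.logpdf(y, loc=loc, scale=s)))
        if fam is Family.TWO_PIECE_SKEW:
            nu = shape["skew"]
            z = np.where(y < loc, nu * (y - loc) / s, (y - loc) / (nu * s))
            logc = np.log(2.0) - np.log(s) - np.log(nu + 1.0 / nu)
            return float(np.sum(logc - 0.5 * np.log(2.0 * np.pi) - 0.5 * z * z))
        # mixture: component means loc + offset_k, SDs scale_k
        comps = []
        for w_k, o_k, s_k in ((shape["weight_1"], shape["offset_1"], shape["scale_1"]),
                              (1 - shape["weight_1"], shape["offset_2"], shape["scale_2"])):
            comps.append(np.log(w_k) + stats.norm.logpdf(y, loc=loc + o_k, scale=s_k))
        return float(np.sum(logsumexp(np.vstack(comps), axis=0)))

    def _penalty_value(self, coef) -> float:
        D = difference_matrix(len(coef), self.penalty_order)
        return float(self.lam_ * np.sum((D @ coef) ** 2))

    def _pll(self, t, y, B, coef, scale_params, shape) -> float:
        return self._loglik(t, y, B @ coef, scale_params, shape) \
            - 0.5 * self._penalty_value(coef)

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ParameterError("X and y must have the same length")
        n = len(y)
        fam = Family(self.family)
        min_n = max(self.degree + 1, 4)
        if n < min_n:
            raise InsufficientDataError(
                f"need at least {min_n} observations, got {n}")
        if np.ptp(t) <= 0:
            raise InsufficientDataError("all observations share a single time point")

        n_knots = min(self.n_interior_knots, max(1, len(np.unique(t)) - 2))
        basis_spec = BasisSpec(float(t.min()), float(t.max()),
                               n_knots, self.degree)
        B = build_basis(basis_spec, t)
        self.basis_spec_ = basis_spec
        self.domain_ = (basis_spec.domain_lo, basis_spec.domain_hi)

        # preliminary Gaussian fit fixes the smoothing weight
        if self.lam is None:
            pen, fit0 = select_lambda_gaic(y, B, self.penalty_order,
                                           k=self.gaic_k, basis_spec=basis_spec)
            self.lam_ = pen.lam
        else:
            self.lam_ = float(self.lam)
            fit0 = fit_penalized_wls(y, B, PenaltySpec(self.penalty_order, self.lam_),
                                     basis_spec=basis_spec)
        coef = fit0.coefficients.copy()
        resid0 = y - B @ coef
        sd0 = float(np.std(resid0))
        floor = max(1e-6 * max(float(np.std(y)), sd0), 1e-12)

        bp = float(self.variance_breakpoint)
        if self.variance == "piecewise_constant" and not (t.min() < bp < t.max()):
            raise ParameterError(
                f"variance breakpoint {bp} must lie inside the observed time "
                f"range [{t.min()}, {t.max()}]")
        scale_params = {
            "constant": {"kind": "constant", "scale": max(sd0, floor)},
            "piecewise_constant": {"kind": "piecewise_constant", "breakpoint": bp,
                                   "scale_low": max(sd0, floor),
                                   "scale_high": max(sd0, floor)},
            "smooth_in_time": {"kind": "smooth_in_time",
                               "a": float(np.log(max(sd0, floor))), "b": 0.0},
        }[self.variance]

        if fam is Family.MIXTURE2:
            coef, scale_params, shape, path, n_iter, conv = self._fit_mixture(
                t, y, B, coef, resid0, floor)
        elif fam is Family.TWO_PIECE_SKEW:
            coef, scale_params, shape, path, n_iter, conv = self._fit_two_piece(
                t, y, B, coef, scale_params, floor)
        else:
            coef, scale_params, shape, path, n_iter, conv = self._fit_normal(
                t, y, B, coef, scale_params, floor)

        self.location_coef_ = coef
        self.scale_params_ = scale_params
        self.shape_params_ = shape
        self.loglik_path_ = np.asarray(path)
        self.n_iter_ = n_iter
        self.converged_ = conv
        self.loglik_ = self._loglik(t, y, B @ coef, scale_params, shape)
        if not np.isfinite(self.loglik_):
            raise FitFailureError("log-likelihood is non-finite at the final iterate")

        # edf: hat-matrix trace at the final working weights + scale/shape params
        w_work = self._working_weights(t, y, B @ coef, scale_params, shape)
        refit = fit_penalized_wls(y, B, PenaltySpec(self.penalty_order, self.lam_),
                                  weights=w_work, basis_spec=basis_spec)
        n_shape = {"normal": 0, "two_piece_skew": 1, "mixture2": 4}[fam.value]
        n_scale = 0 if fam is Family.MIXTURE2 else VarianceSpec(
            self.variance, bp).n_params
        self.location_edf_ = refit.effective_df
        self.edf_ = refit.effective_df + n_scale + n_shape
        self.gaic_ = -2.0 * self.loglik_ + self.gaic_k * self.edf_
        self.n_features_in_ = 1
        return self

    def _working_weights(self, t, y, loc, scale_params, shape):
        fam = Family(self.family)
        s = self._scale_at(t, scale_params)
        if fam is Family.NORMAL:
            return 1.0 / s**2
        if fam is Family.TWO_PIECE_SKEW:
            nu = shape["skew"]
            a = np.where(y < loc, nu * nu, 1.0 / (nu * nu))
            return a / s**2
        g = self._responsibilities(y, loc, shape)
        sc = np.array([shape["scale_1"], shape["scale_2"]])
        return (g / sc**2).sum(axis=1)

    # -- normal -----------------------------------------------------------

    def _fit_normal(self, t, y, B, coef, scale_params, floor):
        pen = PenaltySpec(self.penalty_order, self.lam_)
        shape: dict = {}
        path = [self._pll(t, y, B, coef, scale_params, shape)]
        conv = False
        it = 0
        for it in range(1, self.max_iter + 1):
            s = self._scale_at(t, scale_params)
            fit = fit_penalized_wls(y, B, pen, weights=1.0 / s**2)
            new_coef = fit.coefficients
            new_coef, pll = self._safeguard(t, y, B, coef, new_coef,
                                            scale_params, shape, path[-1])
            coef = new_coef
            resid2 = (y - B @ coef) ** 2
            scale_params = self._update_scale(t, resid2, scale_params, floor)
            pll = self._pll(t, y, B, coef, scale_params, shape)
            path.append(pll)
            if abs(pll - path[-2]) <= self.tol * (abs(path[-2]) + 1.0):
                conv = True
                break
        return coef, scale_params, shape, path, it, conv

    # -- two-piece --------------------------------------------------------

    def _fit_two_piece(self, t, y, B, coef, scale_params, floor):
        pen = PenaltySpec(self.penalty_order, self.lam_)
        shape = {"skew": 1.0}
        path = [self._pll(t, y, B, coef, scale_params, shape)]
        conv = False
        it = 0
        for it in range(1, self.max_iter + 1):
            loc = B @ coef
            nu = shape["skew"]
            s = self._scale_at(t, scale_params)
            a = np.where(y < loc, nu * nu, 1.0 / (nu * nu))
            fit = fit_penalized_wls(y, B, pen, weights=a / s**2)
            coef, _ = self._safeguard(t, y, B, coef, fit.coefficients,
                                      scale_params, shape, path[-1])
            loc = B @ coef
            a = np.where(y < loc, nu * nu, 1.0 / (nu * nu))
            scale_params = self._update_scale(t, a * (y - loc) ** 2,
                                              scale_params, floor)

            def neg_ll(log_nu):
                return -self._loglik(t, y, loc, scale_params, {"skew": np.exp(log_nu)})

            res = minimize_scalar(neg_ll, bounds=(-1.5, 1.5), method="bounded",
                                  options={"xatol": 1e-10})
            cand = {"skew": float(np.exp(res.x))}
            if self._loglik(t, y, loc, scale_params, cand) >= \
                    self._loglik(t, y, loc, scale_params, shape):
                shape = cand
            pll = self._pll(t, y, B, coef, scale_params, shape)
            path.append(pll)
            if abs(pll - path[-2]) <= self.tol * (abs(path[-2]) + 1.0):
                conv = True
                break
        return coef, scale_params, shape, path, it, conv

    def _safeguard(self, t, y, B, coef_old, coef_new, scale_params, shape, pll_old):
        """Step-halve a location update that would decrease the penalized ll."""
        pll_new = self._pll(t, y, B, coef_new, scale_params, shape)
        step = 1.0
        for _ in range(12):
            if pll_new >= pll_old - 1e-10 * (abs(pll_old) + 1.0):
                return coef_new, pll_new
            step /= 2.0
            coef_new = coef_old + step * (coef_new - coef_old)
            pll_new = self._pll(t, y, B, coef_new, scale_params, shape)
        return coef_old, pll_old

    # -- mixture (EM) -----------------------------------------------------

    def _responsibilities(self, y, loc, shape):
        logs = []
        for w_k, o_k, s_k in ((shape["weight_1"], shape["offset_1"], shape["scale_1"]),
                              (1 - shape["weight_1"], shape["offset_2"], shape["scale_2"])):
            logs.append(np.log(w_k) + stats.norm.logpdf(y, loc=loc + o_k, scale=s_k))
        L = np.vstack(logs)  # (2, n)
        g = np.exp(L - logsumexp(L, axis=0))
        return g.T  # (n, 2)

    def _fit_mixture(self, t, y, B, coef0, resid0, floor):
        rng = np.random.default_rng(self.random_state)
        pen = PenaltySpec(self.penalty_order, self.lam_)
        best = None
        for r in range(max(self.n_restarts, 1)):
            if r == 0:
                # split residuals at their lower quintile: the small heavy
                # component captures the left tail
                q = np.quantile(resid0, 0.2)
                g2 = (resid0 < q).astype(float)
            else:
                g2 = rng.uniform(0.1, 0.9, size=len(y))
            g = np.column_stack([1.0 - g2, g2])
            out = self._run_em(t, y, B, coef0.copy(), g, pen, floor)
            if out is None:
                continue
            if best is None or out[3][-1] > best[3][-1]:
                best = out
        if best is None:
            raise FitFailureError("all mixture EM restarts failed")
        return best

    def _run_em(self, t, y, B, coef, g, pen, floor):
        sd0 = max(float(np.std(y - B @ coef)), floor)
        shape = {"weight_1": 0.8, "offset_1": 0.0, "offset_2": 0.0,
                 "scale_1": sd0, "scale_2": sd0}
        scale_params = {"kind": "constant", "scale": sd0}  # placeholder, unused
        path = []
        conv = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # M-step: location spline on mixture working response/weights
            sc = np.array([shape["scale_1"], shape["scale_2"]])
            off = np.array([shape["offset_1"], shape["offset_2"]])
            w_obs = (g / sc**2).sum(axis=1)
            z = ((g / sc**2) * (y[:, None] - off[None, :])).sum(axis=1) / w_obs
            fit = fit_penalized_wls(z, B, pen, weights=w_obs)
            coef = fit.coefficients
            resid = y - B @ coef
            # M-step: weights, offsets, scales
            nk = g.sum(axis=0)
            nk = np.maximum(nk, 1e-8)
            w1 = float(np.clip(nk[0] / len(y), 1e-4, 1 - 1e-4))
            off = (g * resid[:, None]).sum(axis=0) / nk
            s2 = (g * (resid[:, None] - off[None, :]) ** 2).sum(axis=0) / nk
            sc = np.maximum(np.sqrt(s2), floor)
            # re-centre so the location stays the arithmetic mean
            shift = w1 * off[0] + (1 - w1) * off[1]
            coef = coef + shift  # partition of unity: curve shifts by `shift`
            off = off - shift
            shape = {"weight_1": w1, "offset_1": float(off[0]),
                     "offset_2": float(off[1]), "scale_1": float(sc[0]),
                     "scale_2": float(sc[1])}
            pll = self._pll(t, y, B, coef, scale_params, shape)
            if not np.isfinite(pll):
                return None
            path.append(pll)
            # E-step for the next round
            g = self._responsibilities(y, B @ coef, shape)
            if it > 1 and abs(path[-1] - path[-2]) <= self.tol * (abs(path[-2]) + 1.0):
                conv = True
                break
        return coef, scale_params, shape, path, it, conv

    # -- prediction -------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "location_coef_"):
            raise FitFailureError("model is not fitted; call fit() first")

    def _location_at(self, t: np.ndarray) -> np.ndarray:
        lo, hi = self.domain_
        if np.any(t < lo) or np.any(t > hi):
            raise DomainError(
                f"time outside fitted domain [{lo}, {hi}]; no extrapolation")
        return build_basis(self.basis_spec_, t) @ self.location_coef_

    def local_spec(self, t: float) -> DistributionSpec:
        """The fitted concentration distribution at a single time."""
        self._check_fitted()
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        loc = self._location_at(t_arr)[0]
        s = float(self._scale_at(t_arr, self.scale_params_)[0])
        return self._local_spec(loc, s, self.shape_params_)

    def predict(self, X) -> np.ndarray:
        """Fitted arithmetic-mean concentration at the given times."""
        self._check_fitted()
        t = np.asarray(X, dtype=float).reshape(-1)
        loc = self._location_at(t)
        fam = Family(self.family)
        if fam is Family.TWO_PIECE_SKEW:
            s = self._scale_at(t, self.scale_params_)
            nu = self.shape_params_["skew"]
            return loc + np.array([two_piece_mean_offset(si, nu) for si in s])
        return loc

    def predict_quantile(self, X, p: float) -> np.ndarray:
        """p-th concentration quantile at the given times."""
        self._check_fitted()
        t = np.asarray(X, dtype=float).reshape(-1)
        return np.array([dist.quantile(self.local_spec(ti), p) for ti in t])


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over the estimator)
# ---------------------------------------------------------------------------

@dataclass
class FittedTrajectoryModel:
    """A fitted candidate: estimator plus analyte/period bookkeeping."""

    estimator: DistributionalTrajectory
    analyte: str
    period: str
    n_obs: int
    spec: ModelSpec

    @property
    def loglik(self) -> float:
        return self.estimator.loglik_

    @property
    def edf(self) -> float:
        return self.estimator.edf_

    @property
    def aic(self) -> float:
        return self.estimator.gaic_

    @property
    def converged(self) -> bool:
        return self.estimator.converged_

    @property
    def domain(self) -> tuple:
        return self.estimator.domain_

    def mean(self, t) -> np.ndarray:
        return self.estimator.predict(np.atleast_1d(t))

    def local_spec(self, t: float) -> DistributionSpec:
        return self.estimator.local_spec(t)


def fit_trajectory_model(data: ObservationSet, spec: ModelSpec,
                         random_state: int = 0) -> FittedTrajectoryModel:
    """Fit one candidate model to a single-analyte, single-period dataset."""
    analytes = data.frame["analyte"].unique()
    periods = data.frame["period"].unique()
    if len(analytes) != 1 or len(periods) != 1:
        raise ValidationError(
            "fit_trajectory_model requires a single analyte and period; "
            f"got analytes={list(analytes)}, periods={list(periods)}")
    analyte, period = str(analytes[0]), str(periods[0])
    if analyte == "albumin" and len(data) < 30:
        raise InsufficientDataError(
            f"albumin trajectory fits need >= 30 observations, got {len(data)}")
    est = DistributionalTrajectory(
        family=Family(spec.family).value, variance=spec.variance.kind,
        variance_breakpoint=spec.variance.breakpoint,
        n_interior_knots=spec.n_interior_knots, degree=spec.degree,
        penalty_order=spec.penalty_order, lam=spec.lam, gaic_k=spec.gaic_k,
        random_state=random_state)
    est.fit(data.times, data.concentrations)
    return FittedTrajectoryModel(est, analyte, period, len(data), spec)


def gaic(model, k: float = 2.0) -> float:
    """Generalized AIC, ``-2*loglik + k*edf``."""
    est = model.estimator if isinstance(model, FittedTrajectoryModel) else model
    ll = est.loglik_ if hasattr(est, "loglik_") else est.loglik
    edf = est.edf_ if hasattr(est, "edf_") else est.edf
    if not np.isfinite(ll):
        raise FitFailureError("log-likelihood is not finite")
    return -2.0 * ll + k * edf


def select_model(candidates: Sequence, delta: float = 2.034,
                 complexity_key=None):
    """Pick the best candidate by AIC with a parsimony guard.

    Candidates are considered in order of increasing complexity (by ``edf``
    unless ``complexity_key`` is given).  A more complex candidate displaces
    the incumbent only when its AIC is lower by strictly more than ``delta``;
    an advantage of exactly ``delta`` or less is judged minute and the
    simpler model is retained.
    """
    if len(candidates) == 0:
        raise ParameterError("select_model needs at least one candidate")
    key = complexity_key or (lambda m: m.edf if hasattr(m, "edf") else m.edf_)
    ordered = sorted(candidates, key=key)
    aic_of = lambda m: m.aic if hasattr(m, "aic") else m.gaic_
    incumbent = ordered[0]
    for cand in ordered[1:]:
        # strict inequality with an absolute guard: an advantage of exactly
        # delta is judged minute and keeps the simpler incumbent
        if aic_of(incumbent) - aic_of(cand) > delta + 1e-9:
            incumbent = cand
    return incumbent


@dataclass
class QuantileCurveSet:
    """Quantile curves on a time grid; rows are percentiles, columns times."""

    grid: np.ndarray
    percentiles: np.ndarray  # in percent, e.g. 2.5 ... 97.5
    values: np.ndarray       # shape (n_percentiles, n_grid)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=[f"p{p:g}" for p in self.percentiles])
        df.insert(0, "time", self.grid)
        return df


DEFAULT_PERCENTILES = (2.5, 10.0, 25.0, 50.0, 75.0, 90.0, 97.5)


def quantile_curves(model, percentiles=DEFAULT_PERCENTILES,
                    grid=None) -> QuantileCurveSet:
    """Evaluate family quantiles along the fitted trajectory.

    ``percentiles`` are in percent.  Curves are strictly ordered across
    percentiles at every grid time.
    """
    est = model.estimator if isinstance(model, FittedTrajectoryModel) else model
    perc = np.asarray(percentiles, dtype=float)
    if np.any(perc <= 0) or np.any(perc >= 100) or np.any(np.diff(perc) <= 0):
        raise ParameterError("percentiles must be strictly increasing in (0, 100)")
    lo, hi = est.domain_
    if grid is None:
        grid = np.linspace(lo, hi, 101)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < lo) or np.any(grid > hi):
        raise DomainError(f"grid point outside fitted domain [{lo}, {hi}]")
    vals = np.empty((len(perc), len(grid)))
    for j, tj in enumerate(grid):
        spec = est.local_spec(tj)
        vals[:, j] = [dist.quantile(spec, p / 100.0) for p in perc]
    return QuantileCurveSet(grid, perc, vals)


@dataclass
class CoverageTable:
    """Observed percent of data below each model quantile curve."""

    percentiles: np.ndarray
    observed_percent: np.ndarray
    n_obs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"nominal_percentile": self.percentiles,
                             "observed_percent_below": self.observed_percent})


def coverage_table(model, data: ObservationSet,
                   percentiles=DEFAULT_PERCENTILES) -> CoverageTable:
    """Percent of observations strictly below each quantile curve.

    Each observation is compared with the model quantile at its own time;
    a value exactly on the curve counts as not-below (ties are measure-zero
    under these continuous families).
    """
    if len(data) == 0:
        raise ParameterError("coverage_table needs non-empty data")
    est = model.estimator if isinstance(model, FittedTrajectoryModel) else model
    t = data.times
    y = data.concentrations
    perc = np.asarray(percentiles, dtype=float)
    observed = np.empty(len(perc))
    for i, p in enumerate(perc):
        q = est.predict_quantile(t, p / 100.0)
        observed[i] = 100.0 * np.mean(y < q)
    return CoverageTable(perc, observed, len(y))


@dataclass
class ResidualDiagnostics:
    """Normalized quantile residual summary for goodness of fit."""

    residuals: np.ndarray
    mean: float
    variance: float
    qq_deviation: float  # KS distance of residuals from N(0, 1)


def quantile_residual_diagnostics(model, data: ObservationSet) -> ResidualDiagnostics:
    """Normalized quantile residuals r_i = Phi^{-1}(F(y_i | t_i)).

    Under a correctly specified model the residuals are standard normal; the
    ``qq_deviation`` statistic is their Kolmogorov–Smirnov distance from
    N(0, 1).  CDF values at machine 0/1 are clamped with a warning.
    """
    est = model.estimator if isinstance(model, FittedTrajectoryModel) else model
    t = data.times
    y = data.concentrations
    u = np.array([dist.cdf(est.local_spec(ti), yi) for ti, yi in zip(t, y)])
    eps = 1e-12
    if np.any(u <= eps) or np.any(u >= 1 - eps):
        warnings.warn("CDF values at machine 0/1 clamped in quantile residuals",
                      RuntimeWarning, stacklevel=2)
        u = np.clip(u, eps, 1 - eps)
    r = stats.norm.ppf(u)
    ks = stats.kstest(r, "norm").statistic
    var = float(np.var(r)) if len(r) > 1 else 0.0
    return ResidualDiagnostics(r, float(np.mean(r)), var, float(ks))
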