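"""Smoothers: P-splines with difference penalties and GCV smoothing splines.

Two smoother types back the trajectory models:

* Penalized B-splines (P-splines): a cubic B-spline basis on equally spaced
  interior knots, penalized by squared finite differences of adjacent
  coefficients.  Fitting is penalized weighted least squares; model
  complexity is measured by the effective degrees of freedom (edf), the trace
  of the smoother ("hat") matrix.  The smoothing weight lambda is chosen by
  minimizing a generalized AIC, ``n*log(RSS_w/n) + k*edf``, over a log-spaced
  grid with golden-section refinement.

* Natural cubic smoothing splines for sparse analytes: the classic
  roughness-penalized regression with knots at the unique data points, the
  smoothing parameter chosen by generalized cross-validation (GCV).  The
  fitted curve is the natural cubic interpolant of the smoothed values.

Neither smoother extrapolates: evaluation outside the fitted domain raises
``DomainError``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.interpolate import BSpline, CubicSpline

from ._exceptions import (
    DomainError,
    FitFailureError,
    InsufficientDataError,
    ParameterError,
    RankDeficiencyError,
)

__all__ = [
    "BasisSpec",
    "PenaltySpec",
    "SmoothFit",
    "build_basis",
    "difference_matrix",
    "fit_penalized_wls",
    "select_lambda_gaic",
    "fit_cubic_smoothing_spline",
]


@dataclass(frozen=True)
class BasisSpec:
    """Cubic (by default) B-spline basis on equally spaced interior knots."""

    domain_lo: float
    domain_hi: float
    n_interior_knots: int = 20
    degree: int = 3

    def __post_init__(self) -> None:
        if not self.domain_lo < self.domain_hi:
            raise ParameterError(
                f"domain_lo ({self.domain_lo}) must be < domain_hi ({self.domain_hi})")
        if self.n_interior_knots < 1:
            raise ParameterError("n_interior_knots must be >= 1")
        if self.degree < 1:
            raise ParameterError("degree must be >= 1")

    @property
    def n_basis(self) -> int:
        return self.n_interior_knots + self.degree + 1

    def knot_vector(self) -> np.ndarray:
        # uniform knots extended past the domain (no boundary clamping):
        # polynomials of degree < penalty order then lie exactly in the
        # difference-penalty null space
        inner = np.linspace(self.domain_lo, self.domain_hi,
                            self.n_interior_knots + 2)  # exact endpoints
        h = inner[1] - inner[0]
        left = self.domain_lo - h * np.arange(self.degree, 0, -1)
        right = self.domain_hi + h * np.arange(1, self.degree + 1)
        return np.concatenate([left, inner, right])


@dataclass(frozen=True)
class PenaltySpec:
    """Difference penalty of a given order with smoothing weight lambda."""

    order: int = 2
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError("penalty order must be >= 1")
        if self.lam < 0:
            raise ParameterError("lambda must be >= 0")


def build_basis(spec: BasisSpec, times) -> np.ndarray:
    """Dense B-spline design matrix; rows are a partition of unity.

    Raises ``DomainError`` for any time outside ``[domain_lo, domain_hi]`` —
    there is no silent extrapolation.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < spec.domain_lo) or np.any(t > spec.domain_hi):
        bad = t[(t < spec.domain_lo) | (t > spec.domain_hi)]
        raise DomainError(
            f"time(s) {bad[:5]} outside basis domain "
            f"[{spec.domain_lo}, {spec.domain_hi}]")
    knots = spec.knot_vector()
    dm = BSpline.design_matrix(t, knots, spec.degree, extrapolate=False)
    return np.asarray(dm.todense())


def difference_matrix(n_coef: int, order: int) -> np.ndarray:
    """Finite-difference operator D such that D @ c are order-th differences."""
    return np.diff(np.eye(n_coef), n=order, axis=0)


class SmoothFit:
    """A fitted smoother: coefficients, complexity and a curve evaluator."""

    def __init__(self, coefficients: np.ndarray, effective_df: float,
                 evaluate: Callable[[np.ndarray], np.ndarray],
                 domain: tuple[float, float],
                 rss: float, fitted_values: np.ndarray,
                 lam: float = 0.0, gcv: Optional[float] = None):
        self.coefficients = np.asarray(coefficients, dtype=float)
        self.effective_df = float(effective_df)
        self._evaluate = evaluate
        self.domain = (float(domain[0]), float(domain[1]))
        self.rss = float(rss)
        self.fitted_values = np.asarray(fitted_values, dtype=float)
        self.lam = float(lam)
        self.gcv = gcv

    def __call__(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.domain
        if np.any(t_arr < lo) or np.any(t_arr > hi):
            raise DomainError(
                f"evaluation point outside fitted domain [{lo}, {hi}]")
        out = self._evaluate(t_arr)
        return out if np.ndim(t) else float(out[0])


def _normalize_weights(n: int, weights) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ParameterError(f"weights must have shape ({n},), got {w.shape}")
    if np.any(w < 0):
        raise ParameterError("weights must be non-negative")
    if w.sum() <= 0:
        raise ParameterError("weights must not all be zero")
    # mean-one normalization makes the fit invariant to uniform rescaling
    return w * (n / w.sum())


def _pwls_core(y, basis, penalty: PenaltySpec, w):
    B = np.asarray(basis, dtype=float)
    n, m = B.shape
    D = difference_matrix(m, penalty.order)
    P = penalty.lam * (D.T @ D)
    BtW = B.T * w
    A = BtW @ B + P
    if penalty.lam == 0.0:
        rank = np.linalg.matrix_rank(B * np.sqrt(w)[:, None])
        if rank < m:
            raise RankDeficiencyError(
                f"unpenalized design is rank deficient: rank {rank} < {m} columns")
    try:
        # augmented least squares: numerically stable even for huge lambda
        sw = np.sqrt(w)
        X_aug = np.vstack([B * sw[:, None], np.sqrt(penalty.lam) * D])
        z_aug = np.concatenate([sw * y, np.zeros(D.shape[0])])
        coef = np.linalg.lstsq(X_aug, z_aug, rcond=None)[0]
        # edf = trace of the hat matrix = trace(A^-1 B'WB)
        edf = float(np.trace(np.linalg.solve(A, BtW @ B)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - λ>0 keeps A pd
        raise FitFailureError(f"penalized system could not be solved: {exc}") from exc
    fitted = B @ coef
    rss = float(np.sum(w * (y - fitted) ** 2))
    return coef, edf, fitted, rss


def fit_penalized_wls(y, basis, penalty: PenaltySpec, weights=None,
                      basis_spec: Optional[BasisSpec] = None) -> SmoothFit:
    """Penalized weighted least squares on a B-spline (or any) design matrix.

    Minimizes ``sum_i w_i (y_i - B_i c)^2 + lam * ||D c||^2`` where D is the
    order-th difference operator.  Weights are normalized to mean one so a
    uniform rescaling leaves the fit unchanged.
    """
    y = np.asarray(y, dtype=float)
    B = np.asarray(basis, dtype=float)
    if B.shape[0] != y.shape[0]:
        raise ParameterError(
            f"basis has {B.shape[0]} rows but y has {y.shape[0]} entries")
    w = _normalize_weights(len(y), weights)
    coef, edf, fitted, rss = _pwls_core(y, B, penalty, w)
    if basis_spec is not None:
        def evaluate(t, _spec=basis_spec, _c=coef):
            return build_basis(_spec, t) @ _c
        domain = (basis_spec.domain_lo, basis_spec.domain_hi)
    else:
        def evaluate(t):
            raise DomainError(
                "this fit has no basis spec; evaluate through the design matrix")
        domain = (-np.inf, np.inf)
    return SmoothFit(coef, edf, evaluate, domain, rss, fitted, lam=penalty.lam)


def _gaic_of(y, basis, order, w, lam, k):
    _, edf, _, rss = _pwls_core(y, basis, PenaltySpec(order, lam), w)
    n = len(y)
    # floor the RSS so that numerically perfect fits tie across lambdas and
    # the tie resolves to the smoother (larger-lambda) candidate via edf
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    rss = max(rss, 1e-12 * ss_tot, np.finfo(float).tiny)
    return n * np.log(rss / n) + k * edf


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_section(f, lo, hi, n_iter=25):
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(n_iter):
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def select_lambda_gaic(y, basis, order: int = 2, weights=None, k: float = 2.0,
                       lam_grid=None, basis_spec: Optional[BasisSpec] = None):
    """Choose lambda minimizing generalized AIC over a log grid + refinement.

    GAIC is the Gaussian profile criterion ``n*log(RSS_w/n) + k*edf``.  Ties
    resolve to the larger lambda (the smoother fit).  Returns
    ``(PenaltySpec, SmoothFit)``.
    """
    y = np.asarray(y, dtype=float)
    w = _normalize_weights(len(y), weights)
    if lam_grid is None:
        lam_grid = np.logspace(-4, 8, 41)
    lam_grid = np.sort(np.asarray(lam_grid, dtype=float))
    scores = np.array([_gaic_of(y, basis, order, w, lam, k) for lam in lam_grid])
    if not np.all(np.isfinite(scores)):
        raise FitFailureError("non-finite GAIC encountered on the lambda grid")
    # iterate ascending and accept ties: ends on the largest tied lambda
    best_i = 0
    for i in range(1, len(lam_grid)):
        if scores[i] <= scores[best_i]:
            best_i = i
    lo = lam_grid[max(best_i - 1, 0)]
    hi = lam_grid[min(best_i + 1, len(lam_grid) - 1)]
    if lo < hi:
        log_lam = _golden_section(
            lambda ll: _gaic_of(y, basis, order, w, np.exp(ll), k),
            np.log(lo), np.log(hi))
        lam_ref = float(np.exp(log_lam))
        if _gaic_of(y, basis, order, w, lam_ref, k) <= scores[best_i]:
            lam_best = lam_ref
        else:
            lam_best = float(lam_grid[best_i])
    else:
        lam_best = float(lam_grid[best_i])
    pen = PenaltySpec(order, lam_best)
    fit = fit_penalized_wls(y, basis, pen, weights=w, basis_spec=basis_spec)
    return pen, fit


# ---------------------------------------------------------------------------
# natural cubic smoothing spline with GCV
# ---------------------------------------------------------------------------

def _natural_penalty(x: np.ndarray) -> np.ndarray:
    """Roughness matrix K with y'Ky = integral of the second derivative squared."""
    n = len(x)
    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -(1.0 / h[j - 1] + 1.0 / h[j])
        Q[j + 1, j - 1] = 1.0 / h[j]
        R[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            R[j - 1, j] = R[j, j - 1] = h[j] / 6.0
    return Q @ np.linalg.solve(R, Q.T)


def fit_cubic_smoothing_spline(times, values, lam: Optional[float] = None,
                               criterion: str = "gcv") -> SmoothFit:
    """Natural cubic smoothing spline; smoothing chosen by GCV by default.

    Duplicate time points are averaged and re-enter the criterion with
    multiplicity weights.  ``criterion`` may be ``"gcv"`` (default) or
    ``"loocv"`` (ordinary leave-one-out cross-validation); an explicit
    ``lam`` bypasses selection.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise ParameterError("times and values must have matching shapes")
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    xu, inv, counts = np.unique(t, return_inverse=True, return_counts=True)
    if len(xu) < 4:
        raise InsufficientDataError(
            f"smoothing spline needs >= 4 distinct time points, got {len(xu)}")
    yu = np.zeros(len(xu))
    np.add.at(yu, inv, y)
    yu /= counts
    w = counts.astype(float)
    n = len(xu)
    K = _natural_penalty(xu)
    W = np.diag(w)

    def smooth(lam_val):
        A = W + lam_val * K
        S_w = np.linalg.solve(A, W)  # maps yu -> fitted values
        yhat = S_w @ yu
        tr = float(np.trace(S_w))
        rss = float(np.sum(w * (yu - yhat) ** 2))
        return yhat, tr, rss

    n_eff = float(w.sum())

    def score(lam_val):
        yhat, tr, rss = smooth(lam_val)
        if criterion == "gcv":
            denom = max(n_eff - tr, 1e-10)
            return n_eff * rss / denom ** 2
        # LOOCV over unique points via the leverage shortcut
        A = W + lam_val * K
        S_w = np.linalg.solve(A, W)
        resid = yu - S_w @ yu
        lev = np.clip(np.diag(S_w), 0.0, 1.0 - 1e-10)
        return float(np.sum(w * (resid / (1.0 - lev)) ** 2))

    if lam is not None:
        lam_best = float(lam)
    else:
        span = (xu[-1] - xu[0]) ** 3
        grid = np.logspace(-10, 6, 49) * span
        scores = np.array([score(g) for g in grid])
        i = int(np.argmin(scores))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        log_lam = _golden_section(lambda ll: score(np.exp(ll)),
                                  np.log(lo), np.log(hi))
        lam_best = float(np.exp(log_lam))
        if score(grid[i]) < score(lam_best):
            lam_best = float(grid[i])
    yhat, tr, rss = smooth(lam_best)
    # the minimizer is the natural cubic interpolant of the smoothed values
    curve = CubicSpline(xu, yhat, bc_type="natural")
    domain = (float(xu[0]), float(xu[-1]))

    def evaluate(tt, _c=curve):
        return _c(tt)

    return SmoothFit(yhat, tr, evaluate, domain, rss, yhat,
                     lam=lam_best, gcv=score(lam_best))
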