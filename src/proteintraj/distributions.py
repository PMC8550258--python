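"""Error families for distributional trajectory models.

Three location-centred families are supported, matching the error models used
for serum albumin concentrations:

* ``normal`` — the ordinary Gaussian.
* ``mixture2`` — a two-component normal mixture whose components are expressed
  as offsets from a shared location.  The identifiability constraint
  ``w1*offset1 + (1-w1)*offset2 = 0`` makes the location parameter the
  arithmetic mean of the mixture, so a regression on the location is a
  regression on the mean.
* ``two_piece_skew`` — the two-piece ("split" / Fernandez–Steel) normal, often
  called skew-normal type 2.  The density uses a side-dependent scale around
  the mode ``mu``:

      f(y) = c * phi(nu*(y-mu)/sigma)   for y <  mu
      f(y) = c * phi((y-mu)/(nu*sigma)) for y >= mu
      c    = 2 / (sigma * (nu + 1/nu))

  ``nu < 1`` puts more mass below the mode (negative/left skew).  CDF,
  quantile and mean all have closed forms; at ``nu = 1`` the family reduces
  to the normal with the mode as its mean.

All samplers take an explicit seed; there is no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from ._exceptions import ParameterError

__all__ = [
    "Family",
    "NormalParams",
    "MixtureNormal2Params",
    "TwoPieceSkewNormalParams",
    "DistributionSpec",
    "density",
    "cdf",
    "quantile",
    "mean_of",
    "sample",
]

_MIX_CONSTRAINT_TOL = 1e-8


class Family(str, Enum):
    NORMAL = "normal"
    MIXTURE2 = "mixture2"
    TWO_PIECE_SKEW = "two_piece_skew"


@dataclass(frozen=True)
class NormalParams:
    """Gaussian with mean ``location`` and standard deviation ``scale``."""

    location: float
    scale: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.location) and np.isfinite(self.scale)):
            raise ParameterError("normal parameters must be finite")
        if self.scale <= 0:
            raise ParameterError(f"scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class MixtureNormal2Params:
    """Two-component normal mixture centred on its arithmetic mean.

    Component k has mean ``location + offset_k`` and SD ``scale_k``; the
    weighted offsets must cancel so that ``location`` is the mixture mean.
    """

    location: float
    weight_1: float
    offset_1: float
    offset_2: float
    scale_1: float
    scale_2: float

    def __post_init__(self) -> None:
        vals = [self.location, self.weight_1, self.offset_1, self.offset_2,
                self.scale_1, self.scale_2]
        if not all(np.isfinite(v) for v in vals):
            raise ParameterError("mixture parameters must be finite")
        if not (0.0 < self.weight_1 < 1.0):
            raise ParameterError(
                f"weight_1 must lie in the open interval (0, 1), got {self.weight_1}")
        if self.scale_1 <= 0 or self.scale_2 <= 0:
            raise ParameterError("mixture component scales must be > 0")
        resid = self.weight_1 * self.offset_1 + (1 - self.weight_1) * self.offset_2
        tol = _MIX_CONSTRAINT_TOL * max(1.0, abs(self.offset_1), abs(self.offset_2))
        if abs(resid) > tol:
            raise ParameterError(
                "mixture offsets violate the zero-weighted-mean constraint "
                f"(w1*o1 + (1-w1)*o2 = {resid:g})")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.weight_1, 1.0 - self.weight_1])

    @property
    def component_means(self) -> np.ndarray:
        return self.location + np.array([self.offset_1, self.offset_2])

    @property
    def component_scales(self) -> np.ndarray:
        return np.array([self.scale_1, self.scale_2])


@dataclass(frozen=True)
class TwoPieceSkewNormalParams:
    """Two-piece (split) normal around the mode ``mode_location``.

    ``skew`` is the Fernandez–Steel asymmetry parameter nu > 0; nu < 1 gives a
    left (negative) skew, nu = 1 recovers the normal.
    """

    mode_location: float
    scale: float
    skew: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in
                   (self.mode_location, self.scale, self.skew)):
            raise ParameterError("two-piece parameters must be finite")
        if self.scale <= 0:
            raise ParameterError(f"scale must be > 0, got {self.scale}")
        if self.skew <= 0:
            raise ParameterError(f"skew must be > 0, got {self.skew}")


ParamsT = Union[NormalParams, MixtureNormal2Params, TwoPieceSkewNormalParams]

_FAMILY_OF_PARAMS = {
    NormalParams: Family.NORMAL,
    MixtureNormal2Params: Family.MIXTURE2,
    TwoPieceSkewNormalParams: Family.TWO_PIECE_SKEW,
}


@dataclass(frozen=True)
class DistributionSpec:
    """A family tag paired with its matching parameter block."""

    family: Family
    params: ParamsT

    def __post_init__(self) -> None:
        expected = _FAMILY_OF_PARAMS.get(type(self.params))
        if expected is None:
            raise ParameterError(
                f"unrecognized parameter block type {type(self.params).__name__}")
        if Family(self.family) is not expected:
            raise ParameterError(
                f"family tag {self.family!r} does not match parameter block "
                f"{type(self.params).__name__}")


def normal_spec(location: float, scale: float) -> DistributionSpec:
    return DistributionSpec(Family.NORMAL, NormalParams(location, scale))


def mixture2_spec(location: float, weight_1: float, offset_1: float,
                  offset_2: float, scale_1: float, scale_2: float) -> DistributionSpec:
    return DistributionSpec(
        Family.MIXTURE2,
        MixtureNormal2Params(location, weight_1, offset_1, offset_2, scale_1, scale_2),
    )


def two_piece_spec(mode_location: float, scale: float, skew: float) -> DistributionSpec:
    return DistributionSpec(
        Family.TWO_PIECE_SKEW,
        TwoPieceSkewNormalParams(mode_location, scale, skew),
    )


# ---------------------------------------------------------------------------
# two-piece closed forms
# ---------------------------------------------------------------------------

def _tp_norm_const(scale: float, nu: float) -> float:
    return 2.0 / (scale * (nu + 1.0 / nu))


def _tp_density(p: TwoPieceSkewNormalParams, y: np.ndarray) -> np.ndarray:
    mu, s, nu = p.mode_location, p.scale, p.skew
    c = _tp_norm_const(s, nu)
    z = np.where(y < mu, nu * (y - mu) / s, (y - mu) / (nu * s))
    return c * stats.norm.pdf(z)


def _tp_cdf(p: TwoPieceSkewNormalParams, y: np.ndarray) -> np.ndarray:
    mu, s, nu = p.mode_location, p.scale, p.skew
    nsq = nu * nu
    below = (2.0 / (nsq + 1.0)) * stats.norm.cdf(nu * (y - mu) / s)
    above = 1.0 - (2.0 * nsq / (nsq + 1.0)) * stats.norm.sf((y - mu) / (nu * s))
    return np.where(y < mu, below, above)


def _tp_quantile(p: TwoPieceSkewNormalParams, q: np.ndarray) -> np.ndarray:
    mu, s, nu = p.mode_location, p.scale, p.skew
    nsq = nu * nu
    p_mode = 1.0 / (nsq + 1.0)  # CDF mass below the mode
    lower = mu + (s / nu) * stats.norm.ppf(np.minimum(q, p_mode) * (nsq + 1.0) / 2.0)
    upper = mu + s * nu * stats.norm.ppf(
        1.0 - (1.0 - np.maximum(q, p_mode)) * (nsq + 1.0) / (2.0 * nsq))
    return np.where(q <= p_mode, lower, upper)


def _tp_mean(p: TwoPieceSkewNormalParams) -> float:
    nu = p.skew
    return p.mode_location + p.scale * math.sqrt(2.0 / math.pi) * (nu - 1.0 / nu)


def two_piece_mean_offset(scale: float, skew: float) -> float:
    """mean - mode for the two-piece normal: sigma*sqrt(2/pi)*(nu - 1/nu)."""
    return scale * math.sqrt(2.0 / math.pi) * (skew - 1.0 / skew)


# ---------------------------------------------------------------------------
# mixture helpers
# ---------------------------------------------------------------------------

def _mix_cdf(p: MixtureNormal2Params, y: np.ndarray) -> np.ndarray:
    w = p.weights
    means = p.component_means
    scales = p.component_scales
    y = np.asarray(y, dtype=float)
    out = np.zeros(np.shape(y))
    for wk, mk, sk in zip(w, means, scales):
        out = out + wk * stats.norm.cdf(y, loc=mk, scale=sk)
    return out


def _mix_quantile_scalar(p: MixtureNormal2Params, q: float) -> float:
    means = p.component_means
    scales = p.component_scales
    spread = 10.0 * float(scales.max())
    lo = float(means.min()) - spread
    hi = float(means.max()) + spread
    # widen the bracket if an extreme probability falls outside it
    while _mix_cdf(p, np.array(lo)) > q:
        lo -= spread
    while _mix_cdf(p, np.array(hi)) < q:
        hi += spread
    x = brentq(lambda v: float(_mix_cdf(p, np.array(v))) - q, lo, hi,
               xtol=1e-13 * max(1.0, abs(hi), abs(lo)), rtol=8.9e-16)
    return float(x)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def density(spec: DistributionSpec, y) -> np.ndarray:
    """Probability density of ``spec`` at ``y`` (scalar or array)."""
    y_arr = np.asarray(y, dtype=float)
    p = spec.params
    if spec.family is Family.NORMAL:
        out = stats.norm.pdf(y_arr, loc=p.location, scale=p.scale)
    elif spec.family is Family.MIXTURE2:
        out = np.zeros(y_arr.shape)
        for wk, mk, sk in zip(p.weights, p.component_means, p.component_scales):
            out = out + wk * stats.norm.pdf(y_arr, loc=mk, scale=sk)
    else:
        out = _tp_density(p, y_arr)
    return out if np.ndim(y) else float(out)


def cdf(spec: DistributionSpec, y) -> np.ndarray:
    """Cumulative distribution function of ``spec`` at ``y``."""
    y_arr = np.asarray(y, dtype=float)
    p = spec.params
    if spec.family is Family.NORMAL:
        out = stats.norm.cdf(y_arr, loc=p.location, scale=p.scale)
    elif spec.family is Family.MIXTURE2:
        out = _mix_cdf(p, y_arr)
    else:
        out = _tp_cdf(p, y_arr)
    return out if np.ndim(y) else float(out)


def quantile(spec: DistributionSpec, p):
    """Quantile function (inverse CDF); ``p`` must lie strictly in (0, 1)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0.0) or np.any(p_arr >= 1.0):
        raise ParameterError("quantile probabilities must lie strictly in (0, 1)")
    par = spec.params
    if spec.family is Family.NORMAL:
        out = stats.norm.ppf(p_arr, loc=par.location, scale=par.scale)
    elif spec.family is Family.TWO_PIECE_SKEW:
        out = _tp_quantile(par, p_arr)
    else:
        out = np.vectorize(lambda q: _mix_quantile_scalar(par, q))(p_arr)
    return out if np.ndim(p) else float(out)


def mean_of(spec: DistributionSpec) -> float:
    """Arithmetic mean of the distribution."""
    par = spec.params
    if spec.family is Family.NORMAL:
        return par.location
    if spec.family is Family.MIXTURE2:
        # forced by the zero-weighted-offset constraint
        return par.location
    return _tp_mean(par)


def sample(spec: DistributionSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` values; fully reproducible given ``seed``.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ParameterError(f"sample size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    par = spec.params
    if spec.family is Family.NORMAL:
        return rng.normal(par.location, par.scale, size=n)
    if spec.family is Family.MIXTURE2:
        comp = rng.random(n) < par.weight_1
        means = np.where(comp, par.location + par.offset_1, par.location + par.offset_2)
        scales = np.where(comp, par.scale_1, par.scale_2)
        return rng.normal(means, scales)
    mu, s, nu = par.mode_location, par.scale, par.skew
    p_mode = 1.0 / (nu * nu + 1.0)
    below = rng.random(n) < p_mode
    half = np.abs(rng.standard_normal(n))
    return np.where(below, mu - (s / nu) * half, mu + s * nu * half)
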