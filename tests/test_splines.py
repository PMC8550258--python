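"""Smoother correctness: bases, penalized WLS, GAIC selection, smoothing splines."""

import numpy as np
import pytest
from scipy.interpolate import make_smoothing_spline

from proteintraj import splines as sp
from proteintraj._exceptions import (
    DomainError,
    InsufficientDataError,
    ParameterError,
    RankDeficiencyError,
)


# -- basis -------------------------------------------------------------------

@pytest.mark.parametrize("degree, n_knots", [(1, 5), (2, 8), (3, 10), (3, 20)])
def test_basis_rows_are_partition_of_unity(degree, n_knots):
    spec = sp.BasisSpec(0.0, 10.0, n_knots, degree)
    t = np.concatenate([[0.0, 10.0], np.linspace(0.01, 9.99, 57)])
    B = sp.build_basis(spec, t)
    assert B.shape == (len(t), n_knots + degree + 1)
    assert np.max(np.abs(B.sum(axis=1) - 1.0)) < 1e-12
    assert np.all(B >= 0)


def test_basis_rejects_out_of_domain_times():
    spec = sp.BasisSpec(0.0, 10.0, 5, 3)
    for bad in (-0.001, 10.001):
        with pytest.raises(DomainError):
            sp.build_basis(spec, [5.0, bad])


def test_basis_spec_validation():
    with pytest.raises(ParameterError):
        sp.BasisSpec(1.0, 1.0, 5, 3)
    with pytest.raises(ParameterError):
        sp.BasisSpec(0.0, 1.0, 0, 3)
    with pytest.raises(ParameterError):
        sp.PenaltySpec(order=0)
    with pytest.raises(ParameterError):
        sp.PenaltySpec(order=2, lam=-1.0)


# -- penalized WLS -----------------------------------------------------------

def test_unpenalized_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(0)
    t = np.linspace(0, 1, 40)
    X = np.vander(t, 4, increasing=True)  # low-rank polynomial basis
    y = 1 + 2 * t - t**2 + rng.normal(0, 0.1, 40)
    w = rng.uniform(0.5, 2.0, 40)
    fit = sp.fit_penalized_wls(y, X, sp.PenaltySpec(2, 0.0), weights=w)
    # independent dense solve of the weighted normal equations
    w_n = w * len(w) / w.sum()
    oracle = np.linalg.solve(X.T @ (w_n[:, None] * X), X.T @ (w_n * y))
    assert np.max(np.abs(fit.coefficients - oracle)) < 1e-8
    assert fit.effective_df == pytest.approx(4.0, abs=1e-8)


def test_rank_deficiency_reported_at_zero_lambda():
    X = np.column_stack([np.ones(10), np.ones(10)])  # duplicated column
    with pytest.raises(RankDeficiencyError, match="rank 1 < 2"):
        sp.fit_penalized_wls(np.arange(10.0), X, sp.PenaltySpec(1, 0.0))


def test_huge_lambda_order2_reproduces_straight_line():
    spec = sp.BasisSpec(0.0, 10.0, 10, 3)
    t = np.linspace(0, 10, 60)
    y = 2.0 + 0.7 * t  # lies in the order-2 penalty null space
    B = sp.build_basis(spec, t)
    fit = sp.fit_penalized_wls(y, B, sp.PenaltySpec(2, 1e12), basis_spec=spec)
    assert np.max(np.abs(fit.fitted_values - y)) < 1e-6
    assert fit.rss < 1e-8


def test_fit_invariant_to_uniform_weight_rescaling():
    rng = np.random.default_rng(1)
    spec = sp.BasisSpec(0.0, 10.0, 8, 3)
    t = np.linspace(0, 10, 50)
    y = np.sin(t) + rng.normal(0, 0.2, 50)
    B = sp.build_basis(spec, t)
    w = np.ones(50)
    f1 = sp.fit_penalized_wls(y, B, sp.PenaltySpec(2, 3.0), weights=w)
    f2 = sp.fit_penalized_wls(y, B, sp.PenaltySpec(2, 3.0), weights=2.0 * w)
    assert np.allclose(f1.coefficients, f2.coefficients, atol=1e-12)
    assert f1.effective_df == pytest.approx(f2.effective_df, abs=1e-12)


def test_hat_matrix_spectrum_and_edf_monotonicity():
    rng = np.random.default_rng(2)
    spec = sp.BasisSpec(0.0, 10.0, 10, 3)
    t = np.sort(rng.uniform(0, 10, 80))
    B = sp.build_basis(spec, t)
    D = sp.difference_matrix(B.shape[1], 2)
    edfs = []
    for lam in [0.0, 0.1, 10.0, 1e4, 1e8]:
        A = B.T @ B + lam * D.T @ D
        H = B @ np.linalg.solve(A, B.T)
        eig = np.linalg.eigvalsh(H)
        # tolerance reflects the conditioning of the explicit hat product
        assert np.all(eig > -1e-6) and np.all(eig < 1 + 1e-6)
        assert np.trace(H) == pytest.approx(eig.sum(), abs=1e-8)
        fit = sp.fit_penalized_wls(np.sin(t), B, sp.PenaltySpec(2, lam))
        assert fit.effective_df == pytest.approx(np.trace(H), abs=1e-8)
        edfs.append(fit.effective_df)
    assert np.all(np.diff(edfs) < 1e-10), "edf must not increase with lambda"


# -- GAIC lambda selection ---------------------------------------------------

def test_gaic_on_pure_noise_selects_near_null_space_complexity():
    rng = np.random.default_rng(3)
    spec = sp.BasisSpec(0.0, 10.0, 20, 3)
    t = np.sort(rng.uniform(0, 10, 300))
    y = rng.normal(0, 1, 300)  # no trend at all
    B = sp.build_basis(spec, t)
    _, fit = sp.select_lambda_gaic(y, B, order=2)
    assert fit.effective_df <= 2.5


def test_gaic_on_strong_trend_recovers_curve():
    rng = np.random.default_rng(4)
    spec = sp.BasisSpec(0.0, 10.0, 20, 3)
    t = np.sort(rng.uniform(0, 10, 800))
    truth = 5 * np.sin(t)
    y = truth + rng.normal(0, 1.0, 800)
    B = sp.build_basis(spec, t)
    _, fit = sp.select_lambda_gaic(y, B, order=2)
    rmse = np.sqrt(np.mean((fit.fitted_values - truth) ** 2))
    assert rmse < 1.0 / 4.0  # noise SD / 4


def test_equally_good_fits_resolve_to_the_smoother_lambda():
    # a straight line is fit perfectly at every lambda: selection must land
    # in the heavy-smoothing regime rather than an arbitrary small lambda
    spec = sp.BasisSpec(0.0, 10.0, 10, 3)
    t = np.linspace(0, 10, 50)
    y = 1.0 + 0.5 * t
    B = sp.build_basis(spec, t)
    pen, fit = sp.select_lambda_gaic(y, B, order=2)
    assert pen.lam >= 1e4
    assert fit.effective_df == pytest.approx(2.0, abs=0.01)


# -- cubic smoothing spline --------------------------------------------------

def test_smoothing_spline_reproduces_exact_line():
    t = np.linspace(0, 10, 36)
    y = 2.0 + 0.5 * t
    fit = sp.fit_cubic_smoothing_spline(t, y)
    assert np.max(np.abs(fit(t) - y)) < 1e-8


def test_smoothing_spline_tracks_noisy_line_within_two_sd():
    # mirrors the sparse-analyte setting: ~36 points, linear truth
    rng = np.random.default_rng(5)
    t = np.sort(rng.uniform(24, 38, 36))
    truth = 53.6 - 0.669 * (t - 24)
    y = truth + rng.normal(0, 2.0, 36)
    fit = sp.fit_cubic_smoothing_spline(t, y)
    grid = np.linspace(t.min(), t.max(), 100)
    truth_grid = 53.6 - 0.669 * (grid - 24)
    assert np.max(np.abs(fit(grid) - truth_grid)) < 2 * 2.0


def test_smoothing_spline_averages_duplicate_times():
    t = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0])
    y = np.array([0.0, 0.8, 1.2, 2.0, 3.0, 4.0])
    fit = sp.fit_cubic_smoothing_spline(t, y)  # duplicates average to the line
    assert np.max(np.abs(fit(t) - t)) < 1e-6


def test_smoothing_spline_requires_four_distinct_times():
    with pytest.raises(InsufficientDataError):
        sp.fit_cubic_smoothing_spline([0, 1, 1, 2], [0, 1, 1, 2])


def test_smoothing_spline_agrees_with_reference_gcv_implementation():
    rng = np.random.default_rng(6)
    t = np.sort(rng.uniform(0, 10, 60))
    y = np.sin(t) + rng.normal(0, 0.3, 60)
    ours = sp.fit_cubic_smoothing_spline(t, y)
    ref = make_smoothing_spline(t, y)  # independent GCV smoothing spline
    grid = np.linspace(t.min(), t.max(), 120)
    assert np.max(np.abs(ours(grid) - ref(grid))) < 0.1  # well under noise SD


def test_smoothing_spline_consistency_as_n_grows():
    ise = {}
    for n in (50, 500):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 10, n))
        truth = np.sin(t)
        y = truth + rng.normal(0, 0.5, n)
        fit = sp.fit_cubic_smoothing_spline(t, y)
        grid = np.linspace(t.min(), t.max(), 200)
        ise[n] = np.mean((fit(grid) - np.sin(grid)) ** 2)
    assert ise[500] < ise[50]
    assert ise[500] < 0.01


def test_smoothfit_evaluator_refuses_extrapolation():
    t = np.linspace(0, 10, 20)
    fit = sp.fit_cubic_smoothing_spline(t, 2 * t)
    with pytest.raises(DomainError):
        fit(10.5)
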