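"""Trajectory model: fitting, selection, quantile curves, coverage, residuals."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteintraj import distributions as d
from proteintraj._exceptions import (
    InsufficientDataError,
    ParameterError,
    ValidationError,
)
from proteintraj.trajectory import (
    DistributionalTrajectory,
    ModelSpec,
    ObservationSet,
    VarianceSpec,
    coverage_table,
    exclude_outliers,
    fit_trajectory_model,
    gaic,
    quantile_curves,
    quantile_residual_diagnostics,
    select_model,
)

from conftest import linear_truth, make_dataset


def obs(times, values, analyte="albumin", period="pregnancy"):
    return ObservationSet(pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(len(times))],
        "analyte": analyte, "period": period,
        "time": times, "concentration": values}))


# -- observation container ---------------------------------------------------

def test_observation_set_rejects_invalid_records():
    with pytest.raises(ValidationError, match="positive"):
        obs([25.0, 30.0], [34.0, -1.0])
    with pytest.raises(ValidationError, match="analyte"):
        obs([25.0], [34.0], analyte="glucose")
    with pytest.raises(ValidationError, match="pregnancy times"):
        obs([15.0], [34.0])  # before 20 weeks gestation
    with pytest.raises(ValidationError, match="missing"):
        ObservationSet(pd.DataFrame({"time": [1.0]}))


def test_exclude_outliers_counts_and_identity():
    data = obs([25.0, 30.0, 35.0], [34.0, 36.0, 61.0])
    kept, removed = exclude_outliers(data, 60.0)
    assert removed == 1 and len(kept) == 2
    kept2, removed2 = exclude_outliers(data, np.inf)
    assert removed2 == 0 and len(kept2) == 3
    with pytest.raises(ParameterError):
        exclude_outliers(data, 0.0)


# -- fitting and recovery ----------------------------------------------------

def test_normal_fit_recovers_mean_curve(fitted_normal):
    model, t, y, truth = fitted_normal
    rmse = np.sqrt(np.mean((model.predict(t) - truth) ** 2))
    assert rmse < 3.0 / 5.0  # sigma / 5
    assert model.converged_
    assert abs(model.scale_params_["scale"] - 3.0) < 0.3


def test_two_piece_fit_recovers_skew_and_scale(fitted_two_piece):
    model, t, y, truth = fitted_two_piece
    assert 0.6 < model.shape_params_["skew"] < 1.0
    assert abs(model.scale_params_["scale"] - 3.64) / 3.64 < 0.10
    rmse = np.sqrt(np.mean((model.predict(t) - truth) ** 2))
    assert rmse < 3.64 / 5.0


def test_mixture_fit_recovers_mean_curve(fitted_mixture):
    model, t, y, truth = fitted_mixture
    # effective noise SD of the default mixture is ~3.64
    rmse = np.sqrt(np.mean((model.predict(t) - truth) ** 2))
    assert rmse < 3.64 / 5.0
    s = model.shape_params_
    resid = s["weight_1"] * s["offset_1"] + (1 - s["weight_1"]) * s["offset_2"]
    assert abs(resid) < 1e-8, "mixture offsets must keep the location the mean"


def test_piecewise_variance_recovers_both_scales():
    rng = np.random.default_rng(12)
    n = 800
    t = np.sort(rng.uniform(0.0, 46.0, n))
    truth = 42.3 - 10.7 * np.exp(-0.3279 * t)
    sd = np.where(t <= 0.5, 4.86, 3.64)
    y = truth + rng.normal(0, sd)
    m = DistributionalTrajectory(family="normal", variance="piecewise_constant",
                                 variance_breakpoint=0.5).fit(t, y)
    assert abs(m.scale_params_["scale_high"] - 3.64) / 3.64 < 0.10
    # few observations fall in the <=0.5 wk window: loose check only
    assert 2.0 < m.scale_params_["scale_low"] < 9.0


def test_constant_data_yields_constant_mean_and_floored_scale():
    t = np.linspace(20, 42, 50)
    y = np.full(50, 34.0)
    m = DistributionalTrajectory(family="normal").fit(t, y)
    assert np.max(np.abs(m.predict(t) - 34.0)) < 1e-6
    assert m.scale_params_["scale"] < 1e-3


def test_penalized_loglik_is_monotone_for_every_family(
        fitted_normal, fitted_two_piece, fitted_mixture):
    for model, *_ in (fitted_normal, fitted_two_piece, fitted_mixture):
        path = model.loglik_path_
        drops = np.diff(path)
        assert np.all(drops >= -1e-7 * (np.abs(path[:-1]) + 1.0))


def test_mean_curve_equals_family_mean_of_local_spec(fitted_two_piece, fitted_mixture):
    for model, *_ in (fitted_two_piece, fitted_mixture):
        grid = np.linspace(*model.domain_, 25)
        mean_curve = model.predict(grid)
        family_means = [d.mean_of(model.local_spec(g)) for g in grid]
        assert np.max(np.abs(mean_curve - family_means)) < 1e-8


def test_non_convergence_is_reported_not_raised():
    t, y, _ = make_dataset("mixture2", n=200, seed=5)
    m = DistributionalTrajectory(family="mixture2", max_iter=2,
                                 n_restarts=1).fit(t, y)
    assert m.converged_ is False
    assert np.isfinite(m.loglik_)


def test_too_few_observations_raise():
    with pytest.raises(InsufficientDataError):
        DistributionalTrajectory().fit([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(InsufficientDataError):
        DistributionalTrajectory().fit([1.0] * 10, np.arange(10.0))


# -- wrappers: fit_trajectory_model / gaic / select_model --------------------

def test_fit_trajectory_model_validates_input():
    t, y, _ = make_dataset("normal", n=60, seed=8)
    data = obs(t, y)
    mixed = ObservationSet(pd.concat([
        data.frame, obs([25.0], [60.0], analyte="AAG").frame]))
    with pytest.raises(ValidationError, match="single analyte"):
        fit_trajectory_model(mixed, ModelSpec())
    with pytest.raises(InsufficientDataError, match=">= 30"):
        fit_trajectory_model(obs(t[:20], y[:20]), ModelSpec())
    m = fit_trajectory_model(data, ModelSpec())
    assert m.analyte == "albumin" and m.n_obs == 60


def test_gaic_arithmetic():
    fake = SimpleNamespace(loglik=-100.0, edf=5.0)
    assert gaic(fake, k=2.0) == pytest.approx(210.0)
    assert gaic(fake, k=0.0) == pytest.approx(200.0)


def test_nested_model_has_no_worse_deviance():
    t, y, _ = make_dataset("two_piece_skew", n=400, seed=9)
    simple = DistributionalTrajectory(family="normal").fit(t, y)
    complex_ = DistributionalTrajectory(family="two_piece_skew").fit(t, y)
    assert -2 * complex_.loglik_ <= -2 * simple.loglik_ + 1e-6


def test_select_model_parsimony_rule():
    simple = SimpleNamespace(aic=100.0, edf=3.0)
    barely_better = SimpleNamespace(aic=100.0 - 2.034, edf=6.0)
    clearly_better = SimpleNamespace(aic=95.0, edf=6.0)
    # an advantage of exactly delta does not displace the simpler model
    assert select_model([simple, barely_better]) is simple
    assert select_model([simple, clearly_better]) is clearly_better
    assert select_model([simple]) is simple
    with pytest.raises(ParameterError):
        select_model([])


def test_mixture_spec_disallows_extra_variance_structure():
    with pytest.raises(ParameterError):
        ModelSpec(d.Family.MIXTURE2, VarianceSpec("piecewise_constant", 0.5))


def test_family_selection_power_between_normal_and_skew():
    prefer_skew = 0
    prefer_normal = 0
    for seed in range(10):
        t, y, _ = make_dataset("two_piece_skew", n=800, seed=100 + seed)
        cands = [DistributionalTrajectory(family=f).fit(t, y)
                 for f in ("normal", "two_piece_skew")]
        chosen = select_model([SimpleNamespace(aic=c.gaic_, edf=c.edf_, fam=c.family)
                               for c in cands])
        prefer_skew += chosen.fam == "two_piece_skew"
        t, y, _ = make_dataset("normal", n=800, seed=200 + seed)
        cands = [DistributionalTrajectory(family=f).fit(t, y)
                 for f in ("normal", "two_piece_skew")]
        chosen = select_model([SimpleNamespace(aic=c.gaic_, edf=c.edf_, fam=c.family)
                               for c in cands])
        prefer_normal += chosen.fam == "normal"
    assert prefer_skew >= 8
    assert prefer_normal >= 8


# -- quantile curves ---------------------------------------------------------

def test_median_curve_equals_mean_for_normal_family(fitted_normal):
    model, t, *_ = fitted_normal
    grid = np.linspace(*model.domain_, 21)
    qc = quantile_curves(model, percentiles=(50.0,), grid=grid)
    assert np.allclose(qc.values[0], model.predict(grid), atol=1e-10)


def test_left_skew_widens_lower_quantile_spacing(fitted_two_piece):
    model, *_ = fitted_two_piece
    qc = quantile_curves(model, percentiles=(25.0, 50.0, 75.0))
    q25, q50, q75 = qc.values
    assert np.all((q50 - q25) > (q75 - q50))


def test_quantile_curves_strictly_ordered(fitted_mixture):
    model, *_ = fitted_mixture
    qc = quantile_curves(model)
    assert np.all(np.diff(qc.values, axis=0) > 0)
    df = qc.to_frame()
    assert list(df.columns)[0] == "time" and "p97.5" in df.columns


def test_outer_quantiles_bracket_fresh_data(fitted_two_piece):
    model, t, *_ = fitted_two_piece
    rng = np.random.default_rng(77)
    tt = rng.uniform(*model.domain_, 4000)
    fresh = np.array([d.sample(model.local_spec(ti), 1, r)[0]
                      for ti, r in zip(tt, rng.spawn(4000))])
    lo = model.predict_quantile(tt, 0.025)
    hi = model.predict_quantile(tt, 0.975)
    inside = np.mean((fresh > lo) & (fresh < hi))
    assert abs(inside - 0.95) < 0.015


def test_quantile_curve_grid_domain_guard(fitted_normal):
    model, *_ = fitted_normal
    from proteintraj._exceptions import DomainError
    with pytest.raises(DomainError):
        quantile_curves(model, grid=np.array([model.domain_[1] + 1.0]))
    with pytest.raises(ParameterError):
        quantile_curves(model, percentiles=(50.0, 25.0))


# -- coverage ----------------------------------------------------------------

def test_coverage_all_data_below_every_curve(fitted_normal):
    model, t, *_ = fitted_normal
    low = obs(t[:50], np.full(50, 1e-3) + 10.0)
    cov = coverage_table(model, low)
    assert np.allclose(cov.observed_percent, 100.0)


def test_coverage_counts_strictly_below(fitted_normal):
    model, *_ = fitted_normal
    t0 = float(np.mean(model.domain_))
    exact_median = float(model.predict_quantile([t0], 0.5)[0])
    single = obs([t0], [exact_median])
    cov = coverage_table(model, single, percentiles=(50.0,))
    assert cov.observed_percent[0] == 0.0  # on the curve counts as not-below


def test_training_coverage_within_binomial_bounds(fitted_mixture):
    model, t, y, _ = fitted_mixture
    cov = coverage_table(model, obs(t, y))
    n = len(y)
    for nominal, observed in zip(cov.percentiles, cov.observed_percent):
        k = observed / 100.0 * n
        lo = stats.binom.ppf(0.005, n, nominal / 100.0)
        hi = stats.binom.ppf(0.995, n, nominal / 100.0)
        assert lo <= k <= hi, f"coverage at p{nominal} outside binomial bounds"


# -- quantile residuals ------------------------------------------------------

def test_residuals_standard_normal_under_correct_model(fitted_two_piece):
    model, t, y, _ = fitted_two_piece
    diag = quantile_residual_diagnostics(model, obs(t, y))
    assert abs(diag.mean) < 0.1
    assert abs(diag.variance - 1.0) < 0.15


def test_single_observation_at_its_median_has_zero_residual(fitted_normal):
    model, *_ = fitted_normal
    t0 = float(np.mean(model.domain_))
    med = float(model.predict_quantile([t0], 0.5)[0])
    diag = quantile_residual_diagnostics(model, obs([t0], [med]))
    assert diag.residuals[0] == pytest.approx(0.0, abs=1e-7)


def test_wrong_family_inflates_qq_deviation():
    wins = 0
    for seed in range(20):
        t, y, _ = make_dataset("two_piece_skew", n=400, seed=300 + seed, skew=0.6)
        data = obs(t, y)
        good = DistributionalTrajectory(family="two_piece_skew").fit(t, y)
        bad = DistributionalTrajectory(family="normal").fit(t, y)
        ks_good = quantile_residual_diagnostics(good, data).qq_deviation
        ks_bad = quantile_residual_diagnostics(bad, data).qq_deviation
        wins += ks_bad > ks_good
    assert wins >= 16
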