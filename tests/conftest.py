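"""Shared fixtures: small seeded datasets and fitted models reused across tests."""

import numpy as np
import pytest

from proteintraj import distributions as dist
from proteintraj.trajectory import DistributionalTrajectory


def linear_truth(t):
    """Flat-ish gestational albumin mean: 34.3 g/L at 20 wk, 33.4 at 37 wk."""
    return 34.3 - (0.9 / 17.0) * (np.asarray(t) - 20.0)


def make_dataset(family, n=800, seed=0, sigma=3.0, skew=0.8):
    """Times on [20, 42] with noise of the requested family around linear_truth."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(20.0, 42.0, n))
    truth = linear_truth(t)
    if family == "normal":
        y = truth + rng.normal(0.0, sigma, n)
    elif family == "two_piece_skew":
        spec = dist.two_piece_spec(0.0, sigma, skew)
        y = truth + dist.sample(spec, n, rng) - dist.mean_of(spec)
    else:
        spec = dist.mixture2_spec(0.0, 0.8, 0.9, -3.6, 2.5, 5.0)
        y = truth + dist.sample(spec, n, rng)
    return t, y, truth


@pytest.fixture(scope="session")
def fitted_normal():
    t, y, truth = make_dataset("normal", seed=101)
    model = DistributionalTrajectory(family="normal").fit(t, y)
    return model, t, y, truth


@pytest.fixture(scope="session")
def fitted_two_piece():
    t, y, truth = make_dataset("two_piece_skew", seed=202, sigma=3.64)
    model = DistributionalTrajectory(family="two_piece_skew").fit(t, y)
    return model, t, y, truth


@pytest.fixture(scope="session")
def fitted_mixture():
    t, y, truth = make_dataset("mixture2", seed=303)
    model = DistributionalTrajectory(family="mixture2").fit(t, y)
    return model, t, y, truth


@pytest.fixture(scope="session")
def postpartum_artifacts(tmp_path_factory):
    """One full postpartum albumin pipeline run, reused wherever a realistic
    fitted bundle is needed."""
    from proteintraj.io import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("postpartum_run")
    cfg = PipelineConfig(analyte="albumin", period="postpartum", seed=11)
    return run_pipeline(cfg, out), cfg
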