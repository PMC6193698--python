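import numpy as np
import pytest
from hypothesis import settings

from musselfda.smoothing import FunctionalSample

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

GRID = np.linspace(0.0, 150.0, 25)


def gp_curves(n, rng, grid=GRID, length_scale=40.0, scale=1.0):
    """Smooth zero-mean Gaussian-process curves (squared-exponential cov)."""
    d = np.abs(grid[:, None] - grid[None, :])
    K = scale**2 * np.exp(-0.5 * (d / length_scale) ** 2)
    K += 1e-10 * np.trace(K) / len(grid) * np.eye(len(grid))
    return rng.standard_normal((n, len(grid))) @ np.linalg.cholesky(K).T


def make_fs(curves, grid=GRID, ids=None):
    curves = np.atleast_2d(curves)
    ids = list(range(curves.shape[0])) if ids is None else list(ids)
    return FunctionalSample(grid, curves, np.ones(curves.shape[0]), ids)


@pytest.fixture(scope="session")
def grid():
    return GRID


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def default_cohort():
    from musselfda.simulate import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def enriched_cohort(default_cohort):
    from musselfda.energy import derive_all

    meas, diet, truth = default_cohort
    enriched, report = derive_all(meas, diet)
    assert len(report) == 0
    return enriched, truth
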