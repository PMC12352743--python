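import numpy as np
import pytest

from grit import (
    FitConfig,
    SnapshotSeries,
    random_sparse_stable_system,
    simulate_linear_discrete,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_truth():
    """A 10-gene sparse stable system shared by the recovery tests."""
    return random_sparse_stable_system(10, density=0.2, seed=1)


@pytest.fixture(scope="session")
def linear_series(small_truth):
    """Moderate-size discrete-time linear snapshot series (6 times)."""
    return simulate_linear_discrete(small_truth, N=5, dT=1.0, m=400, epsilon=0.2, seed=11)


@pytest.fixture(scope="session")
def fast_config():
    """Entropic regularization matched to the generator noise (0.2)."""
    return FitConfig(
        epsilon=2 * 0.2**2,
        outer_tol=1e-6,
        sinkhorn_tol=1e-6,
        max_outer_iter=120,
    )


@pytest.fixture()
def tiny_series():
    """Two snapshots of three 2-gene cells each, hand-written."""
    Y0 = np.array([[0.0, 1.0, 2.0], [1.0, 1.0, 1.0]])
    Y1 = np.array([[1.0, 2.0, 3.0], [0.5, 1.5, 2.5]])
    return SnapshotSeries(["gA", "gB"], [Y0, Y1], np.array([0.0, 1.0]))
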