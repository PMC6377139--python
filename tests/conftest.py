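import numpy as np
import pytest

from covgraph.cohort import CohortSpec, modular_correlation_target
from covgraph.network import BinaryNetwork


def make_net(adj, d=0.2):
    adj = np.asarray(adj, dtype=np.uint8)
    n = adj.shape[0]
    m = int(adj.sum()) // 2
    actual = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    return BinaryNetwork(adj, d, actual)


def complete_graph(n):
    a = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(a, 0)
    return a


def path_graph(n):
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


def star_graph(n_leaves):
    a = np.zeros((n_leaves + 1, n_leaves + 1), dtype=np.uint8)
    a[0, 1:] = a[1:, 0] = 1
    return a


def cycle_graph(n):
    a = path_graph(n)
    a[0, n - 1] = a[n - 1, 0] = 1
    return a


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """10-ROI, 12v12 two-group cohort spec used across tests."""
    target = modular_correlation_target(10, 2, 0.5, 0.1)
    return CohortSpec(
        n_per_group=(12, 12),
        roi_mean_volumes=np.full(10, 5000.0),
        roi_volume_sd=np.full(10, 500.0),
        correlation_targets={"control": target, "patient": target},
        covariate_distributions={"age": ("normal", 27.0, 7.0),
                                 "sex": ("bernoulli", 0.75)},
        seed=42,
    )
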