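import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_weighted_graph(rng, n_nodes=12, edge_prob=0.4, weighted=True):
    """Erdos-Renyi-style random graph with positive random weights."""
    from ricciphase import WeightedGraph

    pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    keep = rng.random(len(pairs)) < edge_prob
    edges = np.array([p for p, k in zip(pairs, keep) if k], dtype=np.int64).reshape(-1, 2)
    if len(edges) == 0:
        edges = np.array([[0, 1]], dtype=np.int64)
    ew = 0.1 + rng.random(len(edges)) * 5 if weighted else None
    nw = 0.1 + rng.random(n_nodes) * 3 if weighted else None
    return WeightedGraph(range(n_nodes), edges, ew, nw)
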