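"""Synthetic generator contracts: construction arithmetic, statistical
recovery of the attachment kernel, schedule structure, determinism."""

import numpy as np
import networkx as nx
import pytest

from ricciphase import (
    RGNConfig,
    SBMScheduleConfig,
    WMFNConfig,
    WSConfig,
    monofractal_sequence,
    random_growing,
    sbm_sequence,
    watts_strogatz,
    wmfn,
)
from ricciphase._kernels import sample_attachment_targets


class TestRandomGrowing:
    @pytest.mark.parametrize("alpha", [0.0, 1.0, 2.5])
    def test_edge_count_construction_arithmetic(self, alpha):
        n, m0, m = 300, 4, 2
        g = random_growing(RGNConfig(N=n, alpha=alpha, m0=m0, m=m, seed=5))
        assert g.num_edges == m0 * (m0 - 1) // 2 + m * (n - m0)
        assert g.num_nodes == n
        assert g.degrees().sum() == 2 * g.num_edges

    def test_determinism(self):
        cfg = RGNConfig(N=200, alpha=1.0, seed=17)
        a, b = random_growing(cfg), random_growing(cfg)
        assert np.array_equal(a.edges, b.edges)

    def test_simple_graph_invariants(self):
        g = random_growing(RGNConfig(N=500, alpha=3.0, seed=2))
        lo = g.edges.min(axis=1)
        hi = g.edges.max(axis=1)
        assert np.all(lo != hi)  # no self-loops
        assert len(np.unique(lo * g.num_nodes + hi)) == g.num_edges  # no multi-edges

    def test_uniform_attachment_late_degree(self):
        """alpha=0: final degree of arrival i is ~ m + m ln(N/i) in
        expectation (uniform-attachment oracle)."""
        n, m = 400, 2
        degs = []
        for seed in range(30):
            g = random_growing(RGNConfig(N=n, alpha=0.0, m=m, seed=seed))
            degs.append(g.degrees()[200:].mean())  # second-half arrivals
        arrivals = np.arange(200, n)
        expected = (m + m * np.log(n / arrivals)).mean()
        assert np.mean(degs) == pytest.approx(expected, rel=0.1)
        # overall mean degree is 2m up to the seed-graph correction
        assert g.degrees().mean() == pytest.approx(2 * m, rel=0.05)

    def test_ba_tail_exponent(self):
        """alpha=1 recovers the Barabasi-Albert exponent 3 (MLE, k_min=10)."""
        g = random_growing(RGNConfig(N=10_000, alpha=1.0, seed=4))
        k = g.degrees()
        k = k[k >= 10]
        exponent = 1 + len(k) / np.sum(np.log(k / 9.5))
        assert exponent == pytest.approx(3.0, abs=0.3)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 2.0])
    def test_attachment_frequencies_match_kernel(self, alpha):
        """Single-draw frequencies from a fixed 200-node state match
        k^alpha / sum k^alpha within multinomial 3 sigma."""
        rng = np.random.default_rng(31)
        degrees = rng.integers(1, 30, size=200).astype(np.float64)
        probs = degrees**alpha / np.sum(degrees**alpha)
        n_draws = 20_000
        seeds = np.random.SeedSequence(2024).generate_state(n_draws) % 2**31
        counts = np.zeros(200)
        for s in seeds:
            counts[sample_attachment_targets(degrees, 1, alpha, int(s))[0]] += 1
        sigma = np.sqrt(n_draws * probs * (1 - probs))
        # 4-sigma band plus a small-count floor: 200 simultaneous bins
        assert np.all(np.abs(counts - n_draws * probs) <= 4 * sigma + 4)

    def test_uniform_weight_model(self):
        g = random_growing(RGNConfig(N=100, alpha=1.0, weight_model="uniform", seed=0))
        assert np.all((g.edge_weights > 0) & (g.edge_weights <= 1))
        assert len(np.unique(g.edge_weights)) > 50

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            random_growing(RGNConfig(N=3, alpha=1.0, m0=4, m=2))
        with pytest.raises(ValueError):
            random_growing(RGNConfig(N=100, alpha=-0.5))


class TestWattsStrogatz:
    def test_lattice_limit_degree_and_clustering(self):
        k = 6
        g = watts_strogatz(WSConfig(N=100, K=k, p=0.0, seed=0))
        assert np.all(g.degrees() == k)
        expected_cc = 3 * (k - 2) / (4 * (k - 1))
        assert nx.average_clustering(g.to_networkx()) == pytest.approx(expected_cc)

    @pytest.mark.parametrize("p", [0.0, 0.3, 1.0])
    def test_rewiring_preserves_edge_count(self, p):
        cfg = WSConfig(N=200, K=10, p=p, seed=3)
        assert watts_strogatz(cfg).num_edges == 200 * 10 // 2

    def test_random_limit_short_paths(self):
        """p=1: mean shortest path matches an equal-density random graph."""
        g = watts_strogatz(WSConfig(N=1000, K=50, p=1.0, seed=1))
        spl = nx.average_shortest_path_length(g.to_networkx())
        er = nx.gnm_random_graph(1000, g.num_edges, seed=1)
        er_spl = nx.average_shortest_path_length(er)
        assert spl == pytest.approx(er_spl, rel=0.1)
        # and far below the p=0 lattice scale N/(2K)
        assert spl < 0.5 * 1000 / (2 * 50)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            watts_strogatz(WSConfig(N=100, K=5, p=0.1))  # odd K
        with pytest.raises(ValueError):
            watts_strogatz(WSConfig(N=100, K=10, p=1.5))


@pytest.fixture(scope="module")
def sequence():
    return sbm_sequence(SBMScheduleConfig(N=400, T=6, merge_times=(3, 5),
                                          period_sizes=((60, 50, 40, 30), (110, 40, 30), (110, 70)),
                                          seed=7))


class TestSBMSchedule:

    def test_snapshots_binary_symmetric_no_diagonal(self, sequence):
        for g in sequence:
            a = g.to_adjacency()
            assert np.array_equal(a, a.T)
            assert set(np.unique(a)) <= {0.0, 1.0}
            assert np.all(np.diag(a) == 0)

    def test_community_count_schedule(self):
        # 11 communities; two pairwise merges leave 9; merging 7 and 8
        # into 6 collapses three communities into one, leaving 7
        cfg = SBMScheduleConfig()
        assert [len(s) for s in cfg.period_sizes] == [11, 9, 7]
        assert [sum(s) for s in cfg.period_sizes] == [910] * 3
        assert cfg.period_of(1) == 0 and cfg.period_of(11) == 1 and cfg.period_of(21) == 2

    def test_within_community_edge_count_binomial(self):
        """Expected within-community edges ~ p_c * sum C(n_i, 2) before noise."""
        cfg = SBMScheduleConfig(N=400, T=1, merge_times=(), p_s=0.002,
                                period_sizes=((60, 50, 40, 30),), seed=11)
        g = sbm_sequence(cfg)[0]
        pairs = sum(n * (n - 1) // 2 for n in (60, 50, 40, 30))
        expected = cfg.p_c * pairs
        sigma = np.sqrt(pairs * cfg.p_c * (1 - cfg.p_c))
        sizes = (60, 50, 40, 30)
        bounds = np.cumsum((0,) + sizes)
        a = g.to_adjacency()
        within = sum(
            a[bounds[i]:bounds[i + 1], bounds[i]:bounds[i + 1]].sum() / 2
            for i in range(len(sizes))
        )
        # small p_s still perturbs ~ pairs*p_s edges; widen accordingly
        assert abs(within - expected) < 4 * sigma + 2 * pairs * cfg.p_s

    def test_projection_idempotent(self):
        from ricciphase.generators import _project_binary_symmetric

        rng = np.random.default_rng(0)
        m = rng.integers(-1, 3, size=(50, 50))
        once = _project_binary_symmetric(m)
        assert np.array_equal(once, _project_binary_symmetric(once))

    def test_determinism(self):
        cfg = SBMScheduleConfig(N=200, T=3, merge_times=(), period_sizes=((50, 40),), seed=5)
        a = sbm_sequence(cfg)
        b = sbm_sequence(cfg)
        for ga, gb in zip(a, b):
            assert np.array_equal(ga.edges, gb.edges)


class TestWMFN:
    def test_all_ones_gives_complete_graph_with_layer_weight(self):
        r = 2
        ones = tuple(np.ones((2, 2)) for _ in range(r))
        g = wmfn(WMFNConfig(N=40, p_layers=ones, seed=0))
        assert g.num_edges == 40 * 39 // 2
        assert np.all(g.edge_weights == r)

    def test_monofractal_edge_count_binomial(self):
        """Uniform linkage p: every pair connects with probability p^K."""
        p, k, n = 0.4, 2, 120
        pairs = n * (n - 1) / 2
        sigma = np.sqrt(pairs * p**k * (1 - p**k))
        z = [
            (wmfn(WMFNConfig(N=n, p_layers=(np.full((2, 2), p),), K=k, seed=s)).num_edges
             - pairs * p**k) / sigma
            for s in range(40)
        ]
        assert abs(np.mean(z)) < 3 / np.sqrt(40)

    def test_no_self_loops_and_valid_weights(self):
        cfg = WMFNConfig(N=100, p_layers=(np.array([[0.9, 0.3], [0.3, 0.6]]),) * 2, seed=1)
        g = wmfn(cfg)
        assert np.all(g.edges[:, 0] != g.edges[:, 1])
        assert np.all(g.edge_weights >= 1)

    def test_invalid_configs(self):
        with pytest.raises(ValueError, match="sum to 1"):
            wmfn(WMFNConfig(N=10, p_layers=(np.full((2, 2), 0.5),), L=(0.7, 0.2)))
        with pytest.raises(ValueError, match="symmetric"):
            wmfn(WMFNConfig(N=10, p_layers=(np.array([[0.5, 0.1], [0.9, 0.5]]),)))

    def test_monofractal_sequence_stationary_when_unperturbed(self):
        seq = monofractal_sequence(p0=0.2, epsilon=0.0, t_change=5, T=10,
                                   cfg=WMFNConfig(N=150, p_layers=((), ()), K=2), seed=9)
        counts = np.array([g.num_edges for g in seq])
        assert counts.std() < 0.2 * counts.mean()

    def test_monofractal_sequence_perturbation_changes_density(self):
        seq = monofractal_sequence(p0=0.1, epsilon=0.05, t_change=5, T=10,
                                   cfg=WMFNConfig(N=300, p_layers=((), ()), K=3), seed=9)
        counts = np.array([g.num_edges for g in seq])
        # (0.15/0.1)^3 ~ 3.4x edge density after the change
        assert counts[5:].mean() > 2 * counts[:5].mean()

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            monofractal_sequence(p0=0.99, epsilon=0.05, t_change=2, T=4)
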