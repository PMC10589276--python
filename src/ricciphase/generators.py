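"""Seeded synthetic generators for time-varying network case studies.

Four families, each a pure function of (config, seed):

* ``random_growing`` — Barabási–Albert-style growth with the parameterized
  attachment kernel ``p_i = k_i**alpha / sum_j k_j**alpha``; ``alpha = 1``
  recovers the classical linear preferential attachment, ``alpha = 0``
  uniform attachment, and ``alpha > 1`` increasingly hub-dominated graphs.
* ``watts_strogatz`` — ring lattice with per-edge rewiring probability p,
  interpolating regular → small-world → random.
* ``sbm_sequence`` — planted-community stochastic block model sequence:
  a low-rank community matrix L (Bernoulli(p_c) within blocks, held fixed
  within each stable period) plus fresh sparse ±1 noise S each step,
  projected back to a binary symmetric adjacency A(t) = P_Omega[L + S].
  Community merges at fixed times create the phase transitions.
* ``wmfn`` — weighted multifractal networks from K-fold self-similar
  refinement of an interval partition, with R independent linkage layers;
  the edge weight counts the layers in which the pair connected.

Generated edge weights default to 1 (binary snapshots); an optional
i.i.d. Uniform(0, 1] weight model is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import networkx as nx

from ._kernels import grow_preferential_edges
from .graph import SnapshotSequence, WeightedGraph

__all__ = [
    "RGNConfig",
    "WSConfig",
    "SBMScheduleConfig",
    "WMFNConfig",
    "random_growing",
    "watts_strogatz",
    "sbm_sequence",
    "wmfn",
    "monofractal_sequence",
]

#: community sizes of the planted-partition schedule, periods 1..3
_SBM_PERIOD_SIZES = (
    (120, 100, 100, 100, 80, 80, 70, 70, 70, 60, 60),
    (180, 160, 100, 100, 80, 80, 70, 70, 70),  # 10 merged into 0, 9 into 1
    (180, 160, 100, 100, 80, 80, 210),  # 7 and 8 merged into 6
)


def _edge_weights(n_edges: int, weight_model: str | None, rng: np.random.Generator) -> np.ndarray | None:
    if weight_model in (None, "unit"):
        return None
    if weight_model == "uniform":
        # Uniform(0, 1]: strictly positive
        return 1.0 - rng.random(n_edges)
    raise ValueError(f"unknown weight_model {weight_model!r}")


@dataclass(frozen=True)
class RGNConfig:
    """Random growing network: N nodes, complete seed graph on m0, m edges
    per arrival, attachment exponent alpha >= 0."""

    N: int
    alpha: float
    m0: int = 4
    m: int = 2
    weight_model: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (self.m <= self.m0 < self.N):
            raise ValueError("require m <= m0 < N")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def random_growing(cfg: RGNConfig) -> WeightedGraph:
    """Grow one preferential-attachment graph; C(m0,2)+m(N-m0) edges."""
    cfg.validate()
    edges = grow_preferential_edges(cfg.N, cfg.m0, cfg.m, float(cfg.alpha), int(cfg.seed) % (2**31))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,)))
    w = _edge_weights(len(edges), cfg.weight_model, rng)
    return WeightedGraph(range(cfg.N), edges, w, validate=False)


@dataclass(frozen=True)
class WSConfig:
    """Watts–Strogatz small-world network: N nodes, even mean degree K,
    rewiring probability p."""

    N: int
    K: int
    p: float
    weight_model: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.K % 2 or not (0 < self.K < self.N):
            raise ValueError("K must be even and 0 < K < N")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def watts_strogatz(cfg: WSConfig) -> WeightedGraph:
    """Ring lattice with K nearest neighbours, each lattice edge rewired
    with probability p; the edge count N*K/2 is preserved at every p."""
    cfg.validate()
    g = nx.watts_strogatz_graph(cfg.N, cfg.K, cfg.p, seed=int(cfg.seed) % (2**32))
    index = {u: i for i, u in enumerate(g.nodes)}
    edges = np.array([[index[u], index[v]] for u, v in g.edges], dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,)))
    w = _edge_weights(len(edges), cfg.weight_model, rng)
    return WeightedGraph(range(cfg.N), edges, w, validate=False)


@dataclass(frozen=True)
class SBMScheduleConfig:
    """Planted-community SBM schedule with merges at t=11 and t=21.

    Defaults reproduce the three-period study: N=1000, T=30, eleven
    communities (120, 100, 100, 100, 80, 80, 70, 70, 70, 60, 60) plus 90
    background nodes that receive only noise edges, within-community
    density p_c=0.2, and sparse noise with P(S=+1)=P(S=-1)=p_s/2=0.05.
    """

    N: int = 1000
    T: int = 30
    p_c: float = 0.2
    p_s: float = 0.1
    merge_times: tuple[int, ...] = (11, 21)
    period_sizes: tuple[tuple[int, ...], ...] = _SBM_PERIOD_SIZES
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.p_c < 1 and 0 < self.p_s < 1):
            raise ValueError("require 0 < p_c, p_s < 1")
        for sizes in self.period_sizes:
            if sum(sizes) > self.N:
                raise ValueError("community sizes exceed N")
        if len(self.period_sizes) != len(self.merge_times) + 1:
            raise ValueError("one size schedule per stable period required")

    def period_of(self, t: int) -> int:
        """Stable-period index (0-based) of time label t (1-based)."""
        period = 0
        for mt in self.merge_times:
            if t >= mt:
                period += 1
        return period


def _community_matrix(sizes: Sequence[int], n: int, p_c: float, rng: np.random.Generator) -> np.ndarray:
    """Binary low-rank block matrix L: Bernoulli(p_c) within communities."""
    L = np.zeros((n, n), dtype=np.int8)
    start = 0
    for size in sizes:
        block = (rng.random((size, size)) < p_c).astype(np.int8)
        block = np.triu(block, 1)
        L[start : start + size, start : start + size] = block + block.T
        start += size
    return L


def _project_binary_symmetric(m: np.ndarray) -> np.ndarray:
    """P_Omega: clip to {0,1}, mirror the upper triangle, zero diagonal."""
    upper = np.triu(np.clip(m, 0, 1), 1)
    return upper + upper.T


def _graph_from_adjacency_binary(a: np.ndarray) -> WeightedGraph:
    i, j = np.nonzero(np.triu(a, 1))
    edges = np.column_stack([i, j]).astype(np.int64)
    return WeightedGraph(range(a.shape[0]), edges, validate=False)


def sbm_sequence(cfg: SBMScheduleConfig | None = None) -> SnapshotSequence:
    """T binary snapshots A(t) = P_Omega[L(t) + S(t)], labels t = 1..T."""
    cfg = cfg or SBMScheduleConfig()
    cfg.validate()
    root = np.random.SeedSequence(entropy=cfg.seed)
    l_rng = np.random.default_rng(root.spawn(1)[0])
    period_L = [
        _community_matrix(sizes, cfg.N, cfg.p_c, l_rng) for sizes in cfg.period_sizes
    ]
    graphs, labels = [], []
    half = cfg.p_s / 2.0
    for t in range(1, cfg.T + 1):
        s_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2, t))
        )
        u = s_rng.random((cfg.N, cfg.N))
        S = np.where(u < half, 1, np.where(u < cfg.p_s, -1, 0)).astype(np.int8)
        A = _project_binary_symmetric(period_L[cfg.period_of(t)].astype(np.int16) + S)
        graphs.append(_graph_from_adjacency_binary(A))
        labels.append(t)
    return SnapshotSequence(graphs, np.array(labels, dtype=float), require_fixed_nodes=True)


@dataclass(frozen=True)
class WMFNConfig:
    """Weighted multifractal network.

    The unit interval is partitioned into M pieces of lengths L (summing
    to 1) and refined K times self-similarly; every node receives a uniform
    coordinate, and the linkage probability of a pair in layer r is the
    product over the K refinement levels of the layer-r M x M matrix entry
    indexed by the pair's subinterval indices at that level.  One
    independent edge indicator is drawn per layer; the weight of an edge is
    the number of layers that fired.
    """

    N: int
    p_layers: tuple  # R matrices, each M x M, symmetric, entries in [0, 1]
    L: tuple[float, ...] = (0.75, 0.25)
    K: int = 3
    seed: int = 0

    def validate(self) -> None:
        lengths = np.asarray(self.L, dtype=float)
        if np.any(lengths <= 0) or abs(lengths.sum() - 1.0) > 1e-9:
            raise ValueError("interval lengths must be positive and sum to 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        m = len(self.L)
        for p in self.p_layers:
            arr = np.asarray(p, dtype=float)
            if arr.shape != (m, m):
                raise ValueError("each linkage matrix must be M x M")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError("linkage probabilities must lie in [0, 1]")
            if not np.allclose(arr, arr.T):
                raise ValueError("linkage matrices must be symmetric")


def _refinement_indices(coords: np.ndarray, lengths: np.ndarray, depth: int) -> np.ndarray:
    """(N, K) subinterval index of each coordinate at each refinement level."""
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    cum[-1] = 1.0
    t = np.clip(coords, 0.0, np.nextafter(1.0, 0.0))
    idx = np.empty((len(coords), depth), dtype=np.int64)
    for k in range(depth):
        cell = np.clip(np.searchsorted(cum, t, side="right") - 1, 0, len(lengths) - 1)
        idx[:, k] = cell
        t = (t - cum[cell]) / lengths[cell]
        t = np.clip(t, 0.0, np.nextafter(1.0, 0.0))
    return idx


def wmfn(cfg: WMFNConfig) -> WeightedGraph:
    """One multifractal snapshot; absent pairs have weight 0 (no edge)."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed))
    lengths = np.asarray(cfg.L, dtype=float)
    coords = rng.random(cfg.N)
    idx = _refinement_indices(coords, lengths, cfg.K)
    weight = np.zeros((cfg.N, cfg.N), dtype=np.int64)
    for p in cfg.p_layers:
        arr = np.asarray(p, dtype=float)
        prob = np.ones((cfg.N, cfg.N))
        for k in range(cfg.K):
            prob *= arr[idx[:, k][:, None], idx[:, k][None, :]]
        fired = rng.random((cfg.N, cfg.N)) < prob
        weight += np.triu(fired, 1)
    i, j = np.nonzero(weight)
    edges = np.column_stack([i, j]).astype(np.int64)
    return WeightedGraph(range(cfg.N), edges, weight[i, j].astype(float), validate=False)


def monofractal_sequence(
    p0: float,
    epsilon: float,
    t_change: int,
    T: int,
    cfg: WMFNConfig | None = None,
    seed: int = 0,
) -> SnapshotSequence:
    """Monofractal perturbation study: uniform linkage probability p0 for
    t < t_change and p0 + epsilon from t_change on, fresh randomness per
    snapshot.  Labels are t = 0..T-1."""
    base = cfg or WMFNConfig(N=1000, p_layers=((), ()))
    m = len(base.L)
    n_layers = max(1, len(base.p_layers))
    for p in (p0, p0 + epsilon):
        if not (0.0 <= p <= 1.0):
            raise ValueError("linkage probabilities must lie in [0, 1]")
    graphs, labels = [], []
    for t in range(T):
        p = p0 if t < t_change else p0 + epsilon
        layer = tuple(np.full((m, m), p) for _ in range(n_layers))
        snap_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(t,)).generate_state(1)[0]
        )
        graphs.append(
            wmfn(WMFNConfig(N=base.N, p_layers=layer, L=base.L, K=base.K, seed=snap_seed))
        )
        labels.append(t)
    return SnapshotSequence(graphs, np.array(labels, dtype=float), require_fixed_nodes=True)
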