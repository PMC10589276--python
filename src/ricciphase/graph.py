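"""Weighted undirected graph data model.

The package works on simple undirected graphs with strictly positive edge
weights and (optional) strictly positive node weights.  Internally nodes are
mapped to contiguous integer indices and edges are stored as a ``(E, 2)``
index array plus a weight vector, so curvature computation stays fully
vectorized; :mod:`networkx` interoperability is provided for everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import networkx as nx

__all__ = ["WeightedGraph", "SnapshotSequence"]


class WeightedGraph:
    """Simple undirected graph with positive edge and node weights.

    Parameters
    ----------
    nodes
        Sequence of hashable node identifiers (order defines the index).
    edges
        ``(E, 2)`` integer array of node *indices* (one row per undirected
        edge, each unordered pair at most once, no self-loops).
    edge_weights
        ``(E,)`` strictly positive weights; defaults to all ones.
    node_weights
        ``(N,)`` strictly positive weights; defaults to all ones
        (the standard combinatorial convention).
    """

    __slots__ = ("nodes", "_index", "edges", "edge_weights", "node_weights")

    def __init__(
        self,
        nodes: Sequence[Hashable],
        edges: np.ndarray,
        edge_weights: np.ndarray | None = None,
        node_weights: np.ndarray | None = None,
        validate: bool = True,
    ) -> None:
        self.nodes = list(nodes)
        self._index = {u: i for i, u in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        n = len(self.nodes)
        if edge_weights is None:
            edge_weights = np.ones(len(edges))
        if node_weights is None:
            node_weights = np.ones(n)
        self.edges = edges
        self.edge_weights = np.asarray(edge_weights, dtype=float)
        self.node_weights = np.asarray(node_weights, dtype=float)
        if validate:
            self._validate()

    def _validate(self) -> None:
        n, e = len(self.nodes), len(self.edges)
        if self.edge_weights.shape != (e,):
            raise ValueError("edge_weights length mismatch")
        if self.node_weights.shape != (n,):
            raise ValueError("node_weights length mismatch")
        if e:
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge index out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            lo = self.edges.min(axis=1)
            hi = self.edges.max(axis=1)
            key = lo * n + hi
            if len(np.unique(key)) != e:
                raise ValueError("duplicate edge (multi-edges are not allowed)")
        if not np.all(np.isfinite(self.edge_weights)) or np.any(self.edge_weights <= 0):
            raise ValueError("invalid weight: edge weights must be finite and > 0")
        if not np.all(np.isfinite(self.node_weights)) or np.any(self.node_weights <= 0):
            raise ValueError("invalid weight: node weights must be finite and > 0")

    # -- basic queries ---------------------------------------------------

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        """Unweighted degree of every node (index order)."""
        deg = np.zeros(self.num_nodes, dtype=np.int64)
        if self.num_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def edge_index(self, u: Hashable, v: Hashable) -> int:
        """Row index of edge ``{u, v}``; raises if absent."""
        try:
            i, j = self._index[u], self._index[v]
        except KeyError as exc:
            raise KeyError(f"edge not in graph: node {exc} unknown") from None
        mask = ((self.edges[:, 0] == i) & (self.edges[:, 1] == j)) | (
            (self.edges[:, 0] == j) & (self.edges[:, 1] == i)
        )
        rows = np.flatnonzero(mask)
        if not len(rows):
            raise KeyError(f"edge not in graph: ({u!r}, {v!r})")
        return int(rows[0])

    def edge_weight(self, u: Hashable, v: Hashable) -> float:
        """Weight of edge ``{u, v}``; raises if absent."""
        return float(self.edge_weights[self.edge_index(u, v)])

    def has_edge(self, u: Hashable, v: Hashable) -> bool:
        try:
            self.edge_index(u, v)
            return True
        except KeyError:
            return False

    def edge_pairs(self) -> Iterable[tuple[Hashable, Hashable, float]]:
        """Iterate ``(u, v, weight)`` with original node identifiers."""
        for (i, j), w in zip(self.edges, self.edge_weights):
            yield self.nodes[i], self.nodes[j], float(w)

    # -- constructors / converters --------------------------------------

    @classmethod
    def from_edge_pairs(
        cls,
        pairs: Iterable[tuple[Hashable, Hashable, float]],
        nodes: Sequence[Hashable] | None = None,
        node_weights: dict | None = None,
    ) -> "WeightedGraph":
        pairs = list(pairs)
        if nodes is None:
            seen: dict[Hashable, None] = {}
            for u, v, _ in pairs:
                seen.setdefault(u)
                seen.setdefault(v)
            nodes = list(seen)
        index = {u: i for i, u in enumerate(nodes)}
        edges = np.array([[index[u], index[v]] for u, v, _ in pairs], dtype=np.int64).reshape(-1, 2)
        weights = np.array([w for _, _, w in pairs], dtype=float)
        nw = None
        if node_weights is not None:
            nw = np.array([node_weights.get(u, 1.0) for u in nodes], dtype=float)
        return cls(nodes, edges, weights, nw)

    @classmethod
    def from_networkx(cls, g: "nx.Graph", weight: str = "weight") -> "WeightedGraph":
        if g.is_directed():
            raise ValueError("directed graphs are rejected; symmetrize explicitly first")
        if g.is_multigraph():
            raise ValueError("multi-edges are not allowed")
        nodes = list(g.nodes)
        index = {u: i for i, u in enumerate(nodes)}
        edges = np.array([[index[u], index[v]] for u, v in g.edges], dtype=np.int64).reshape(-1, 2)
        w = np.array([d.get(weight, 1.0) for _, _, d in g.edges(data=True)], dtype=float)
        nw = np.array([g.nodes[u].get(weight, 1.0) for u in nodes], dtype=float)
        return cls(nodes, edges, w, nw)

    def to_networkx(self) -> "nx.Graph":
        g = nx.Graph()
        for u, w in zip(self.nodes, self.node_weights):
            g.add_node(u, weight=float(w))
        for u, v, w in self.edge_pairs():
            g.add_edge(u, v, weight=w)
        return g

    def to_adjacency(self) -> np.ndarray:
        """Dense symmetric weight matrix in node-index order."""
        a = np.zeros((self.num_nodes, self.num_nodes))
        i, j = self.edges[:, 0], self.edges[:, 1]
        a[i, j] = self.edge_weights
        a[j, i] = self.edge_weights
        return a

    def __repr__(self) -> str:  # pragma: no cover
        return f"WeightedGraph(n={self.num_nodes}, m={self.num_edges})"


@dataclass
class SnapshotSequence:
    """Ordered sequence of graph snapshots with strictly increasing labels.

    Labels are either integer time indices or real sweep-parameter values.
    """

    graphs: list[WeightedGraph]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    require_fixed_nodes: bool = False

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = np.arange(len(self.graphs))
        self.labels = np.asarray(self.labels, dtype=float)
        if len(self.labels) != len(self.graphs):
            raise ValueError("one label per snapshot required")
        if len(self.labels) > 1 and not np.all(np.diff(self.labels) > 0):
            raise ValueError("labels must be strictly increasing")
        if self.require_fixed_nodes and self.graphs:
            universe = self.graphs[0].nodes
            for g in self.graphs[1:]:
                if g.nodes != universe:
                    raise ValueError("snapshots must share the node universe")

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(self.graphs)

    def __getitem__(self, i: int) -> WeightedGraph:
        return self.graphs[i]
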