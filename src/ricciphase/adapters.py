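"""Graph I/O and real-data preprocessing adapters.

Formats
-------
* Edge list: plain text, one edge per line ``u<TAB>v<TAB>w`` (any
  whitespace accepted on read); lines starting with ``#`` are ignored;
  node ids are arbitrary strings; weights decimal.
* Dense matrix: whitespace- or comma-separated square numeric matrix,
  symmetric within tolerance; the diagonal is ignored and zero entries
  mean "no edge".  This is also how per-chromosome Hi-C contact matrices
  enter: loci are nodes and contact counts are edge weights (optionally
  log1p-compressed).

Preprocessing recipes
---------------------
* ``mlp_to_graph`` — a multilayer perceptron's inter-layer weight matrices
  become a layered undirected graph; edge weights are the min–max
  normalized magnitudes of the connection weights within one training
  snapshot (the minimum entry normalizes to 0 and is dropped).
* ``vote_agreement_sequence`` — a binary seat x vote roll-call matrix is
  folded into consecutive blocks; each block's pairwise same-vote
  fraction becomes a weighted agreement network, one snapshot per block.

Readers reject malformed input rather than repairing it; every writer's
output re-reads identically.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .graph import SnapshotSequence, WeightedGraph

__all__ = [
    "LayeredWeights",
    "read_edge_list",
    "write_edge_list",
    "read_dense_matrix",
    "matrix_to_graph",
    "minmax_normalize",
    "mlp_to_graph",
    "vote_agreement_sequence",
    "write_snapshot_sequence",
    "read_snapshot_sequence",
]


def read_edge_list(path) -> WeightedGraph:
    """Parse a ``u v w`` edge-list file; malformed lines raise with the
    offending line number."""
    pairs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'u v w', got {line!r}")
            u, v, w_str = parts
            try:
                w = float(w_str)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: weight {w_str!r} is not a number") from None
            pairs.append((u, v, w))
    try:
        return WeightedGraph.from_edge_pairs(pairs)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_edge_list(g: WeightedGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# u\tv\tw\n")
        for u, v, w in g.edge_pairs():
            fh.write(f"{u}\t{v}\t{w!r}\n")


def read_dense_matrix(path) -> np.ndarray:
    """Square numeric matrix from whitespace- or comma-separated text."""
    text = Path(path).read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    matrix = np.loadtxt(path, delimiter=delimiter)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{path}: matrix must be square, got shape {matrix.shape}")
    return matrix


def matrix_to_graph(
    matrix: np.ndarray,
    symmetric_tol: float = 1e-9,
    log1p: bool = False,
    nodes: Sequence | None = None,
) -> WeightedGraph:
    """Weighted graph from a symmetric nonnegative matrix.

    Off-diagonal positive entries become edges (diagonal ignored); the
    optional ``log1p`` flag compresses heavy-tailed contact counts.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if np.max(np.abs(a - a.T)) > symmetric_tol:
        raise ValueError(f"matrix is not symmetric within tolerance {symmetric_tol}")
    if np.any(a < 0):
        raise ValueError("matrix entries must be nonnegative")
    n = a.shape[0]
    upper = np.triu(a, 1)
    i, j = np.nonzero(upper)
    w = upper[i, j]
    if log1p:
        w = np.log1p(w)
    node_ids = list(nodes) if nodes is not None else list(range(n))
    if len(node_ids) != n:
        raise ValueError("one node id per matrix row required")
    edges = np.column_stack([i, j]).astype(np.int64)
    return WeightedGraph(node_ids, edges, w)


def minmax_normalize(values) -> np.ndarray:
    """Affine rescaling ``(x - min) / (max - min)`` onto [0, 1]."""
    x = np.asarray(values, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("degenerate range: all values identical")
    return (x - lo) / (hi - lo)


@dataclass
class LayeredWeights:
    """Ordered inter-layer weight matrices of a multilayer perceptron.

    ``matrices[k]`` has shape (size of layer k, size of layer k+1); adjacent
    shapes must chain consistently.
    """

    matrices: list[np.ndarray]

    def __post_init__(self) -> None:
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        if not self.matrices:
            raise ValueError("at least one weight matrix required")
        for a, b in zip(self.matrices, self.matrices[1:]):
            if a.shape[1] != b.shape[0]:
                raise ValueError(
                    f"dimension mismatch: {a.shape} does not chain with {b.shape}"
                )

    def layer_sizes(self) -> list[int]:
        return [self.matrices[0].shape[0]] + [m.shape[1] for m in self.matrices]


def mlp_to_graph(w: LayeredWeights) -> WeightedGraph:
    """Layered graph of one training snapshot.

    Edge weights are min–max normalized |connection weight| over the whole
    snapshot; the minimum entry (normalized weight 0) is dropped so all
    edge weights stay strictly positive.  Nodes are labelled
    ``(layer, unit)``.
    """
    mags = [np.abs(m) for m in w.matrices]
    flat = np.concatenate([m.ravel() for m in mags])
    normalized = minmax_normalize(flat)
    sizes = w.layer_sizes()
    nodes = [(layer, unit) for layer, size in enumerate(sizes) for unit in range(size)]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    pairs = []
    pos = 0
    for layer, m in enumerate(mags):
        block = normalized[pos : pos + m.size].reshape(m.shape)
        pos += m.size
        i, j = np.nonzero(block > 0)
        for a, b in zip(i, j):
            pairs.append(((layer, int(a)), (layer + 1, int(b)), float(block[a, b])))
    return WeightedGraph.from_edge_pairs(pairs, nodes=nodes)


def vote_agreement_sequence(votes: np.ndarray, block_size: int = 240) -> SnapshotSequence:
    """Agreement networks from a binary seats x votes roll-call matrix.

    Per vote, two seats agree when they cast the same value; each
    consecutive block of ``block_size`` votes is averaged entrywise into a
    weighted graph whose edge weight is the within-block agreement
    probability (weight-0 pairs carry no edge).  Snapshot labels are the
    1-based block indices.
    """
    v = np.asarray(votes)
    if v.ndim != 2:
        raise ValueError("vote matrix must be seats x votes")
    if not np.isin(v, (0, 1)).all():
        raise ValueError("vote matrix entries must be binary (0/1)")
    n_seats, n_votes = v.shape
    if n_votes < block_size:
        raise ValueError("need at least one full block of votes")
    v = v.astype(float)
    n_blocks = n_votes // block_size
    graphs, labels = [], []
    for b in range(n_blocks):
        block = v[:, b * block_size : (b + 1) * block_size]
        # agreement count = matches on 1s plus matches on 0s
        agree = block @ block.T + (1 - block) @ (1 - block).T
        weight = agree / block_size
        np.fill_diagonal(weight, 0.0)
        i, j = np.nonzero(np.triu(weight, 1))
        edges = np.column_stack([i, j]).astype(np.int64)
        graphs.append(WeightedGraph(range(n_seats), edges, weight[i, j]))
        labels.append(b + 1)
    return SnapshotSequence(graphs, np.array(labels, dtype=float), require_fixed_nodes=True)


def write_snapshot_sequence(seq: SnapshotSequence, directory, prefix: str = "snapshot") -> Path:
    """Write numbered edge-list files plus a JSON manifest; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for k, (g, label) in enumerate(zip(seq.graphs, seq.labels)):
        name = f"{prefix}_{k:04d}.tsv"
        write_edge_list(g, directory / name)
        manifest.append({"label": float(label), "path": name})
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_snapshot_sequence(manifest_path) -> SnapshotSequence:
    manifest_path = Path(manifest_path)
    entries = json.loads(manifest_path.read_text())
    graphs = [read_edge_list(manifest_path.parent / e["path"]) for e in entries]
    labels = np.array([e["label"] for e in entries], dtype=float)
    return SnapshotSequence(graphs, labels)
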