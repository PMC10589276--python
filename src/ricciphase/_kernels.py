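"""Compiled inner loops for the growing-network generator.

Weighted sampling without replacement over the attachment kernel
``k_i**alpha`` is the only part of the package that is sequential by nature
(degrees change after every arrival), so it is JIT-compiled.  Node weights
live in a Fenwick (binary indexed) tree holding partial sums, giving
O(log N) per draw and per degree update.

Degrees never exceed N <= ~1e6 and alpha stays O(10) in every study, so
``k**alpha`` is computed directly in float64 (max ~1e60, far from overflow).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["grow_preferential_edges", "sample_attachment_targets"]


@njit(cache=True)
def _fenwick_add(tree, i, delta):
    # tree is 1-indexed; slot 0 unused
    n = tree.shape[0] - 1
    i += 1
    while i <= n:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _fenwick_total(tree):
    total = 0.0
    n = tree.shape[0] - 1
    i = n
    while i > 0:
        total += tree[i]
        i -= i & (-i)
    return total


@njit(cache=True)
def _fenwick_sample(tree, weights, u):
    """Index with cumulative weight bracketing ``u * total``; O(log N)."""
    n = tree.shape[0] - 1
    target = u * _fenwick_total(tree)
    pos = 0
    bitmask = 1
    while bitmask * 2 <= n:
        bitmask *= 2
    while bitmask > 0:
        nxt = pos + bitmask
        if nxt <= n and tree[nxt] < target:
            pos = nxt
            target -= tree[nxt]
        bitmask //= 2
    idx = pos  # 0-indexed node
    if idx >= weights.shape[0]:
        idx = weights.shape[0] - 1
    # guard against landing on a zero-weight slot at floating-point edges
    while idx < weights.shape[0] - 1 and weights[idx] <= 0.0:
        idx += 1
    while idx > 0 and weights[idx] <= 0.0:
        idx -= 1
    return idx


@njit(cache=True)
def grow_preferential_edges(n_nodes, m0, m, alpha, seed):
    """Edge array of a preferential-attachment growth with kernel k**alpha.

    Starts from a complete graph on ``m0`` nodes; every arriving node
    attaches to ``m`` distinct existing nodes drawn without replacement
    with probability proportional to ``degree**alpha`` (probabilities
    renormalized after each draw by zeroing the chosen slot).
    """
    np.random.seed(seed)
    n_edges = m0 * (m0 - 1) // 2 + m * (n_nodes - m0)
    edges = np.empty((n_edges, 2), dtype=np.int64)
    deg = np.zeros(n_nodes, dtype=np.int64)
    weights = np.zeros(n_nodes)
    tree = np.zeros(n_nodes + 1)

    k = 0
    for i in range(m0):
        for j in range(i + 1, m0):
            edges[k, 0] = i
            edges[k, 1] = j
            k += 1
        deg[i] = m0 - 1
    for i in range(m0):
        weights[i] = float(deg[i]) ** alpha
        _fenwick_add(tree, i, weights[i])

    targets = np.empty(m, dtype=np.int64)
    for new in range(m0, n_nodes):
        for t in range(m):
            u = np.random.random()
            chosen = _fenwick_sample(tree, weights, u)
            targets[t] = chosen
            _fenwick_add(tree, chosen, -weights[chosen])  # exclude from this round
            weights[chosen] = 0.0
        for t in range(m):
            chosen = targets[t]
            deg[chosen] += 1
            weights[chosen] = float(deg[chosen]) ** alpha
            _fenwick_add(tree, chosen, weights[chosen])
            edges[k, 0] = chosen
            edges[k, 1] = new
            k += 1
        deg[new] = m
        weights[new] = float(m) ** alpha
        _fenwick_add(tree, new, weights[new])
    return edges


@njit(cache=True)
def sample_attachment_targets(degrees, m, alpha, seed):
    """One attachment round: m distinct targets drawn with kernel k**alpha.

    Exposed separately so the empirical attachment frequencies of the
    kernel can be validated against ``k**alpha / sum k**alpha`` directly.
    """
    np.random.seed(seed)
    n = degrees.shape[0]
    weights = np.empty(n)
    tree = np.zeros(n + 1)
    for i in range(n):
        weights[i] = float(degrees[i]) ** alpha
        _fenwick_add(tree, i, weights[i])
    targets = np.empty(m, dtype=np.int64)
    for t in range(m):
        u = np.random.random()
        chosen = _fenwick_sample(tree, weights, u)
        targets[t] = chosen
        _fenwick_add(tree, chosen, -weights[chosen])
        weights[chosen] = 0.0
    return targets
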