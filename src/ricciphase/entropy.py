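"""Forman–Ricci network entropy and Monte-Carlo sweep traces.

The state descriptor of a snapshot is the Shannon differential entropy of
its edge-curvature distribution,

    H_R(G) = - \\int f_RC(x) log2 f_RC(x) dx   [bits],

with ``f_RC`` the wavelet density estimate of the curvature samples.  Being
differential, H_R may be negative for concentrated distributions; shifting
all curvatures leaves it unchanged and scaling by ``a`` adds ``log2 a``.

``entropy_sweep`` drives a seeded generator over a parameter grid with R
Monte-Carlo realizations per value and returns the mean trace with a
normal-approximation 95% confidence band (mean ± 1.96 s/√R).  All
randomness descends from a single root seed split by (value, realization)
index, so enlarging R never reshuffles earlier realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .curvature import CurvatureField, forman_ricci_all
from .density import DensityConfig, DensityEstimate, estimate_density
from .graph import SnapshotSequence, WeightedGraph

__all__ = [
    "EntropyTrace",
    "differential_entropy_bits",
    "network_entropy",
    "entropy_sweep",
    "entropy_over_sequence",
    "trace_from_realizations",
    "realization_seed",
]

_CI_Z = 1.96  # two-sided 95% normal quantile


def differential_entropy_bits(estimate: DensityEstimate) -> float:
    """Trapezoid quadrature of ``-f log2 f`` over the estimate's grid."""
    f = estimate.values
    integrand = np.zeros_like(f)
    positive = f > 0
    integrand[positive] = -f[positive] * np.log2(f[positive])
    return float(np.trapezoid(integrand, estimate.grid))


def network_entropy(c: CurvatureField | np.ndarray, density_config: DensityConfig | None = None) -> float:
    """Forman–Ricci network entropy of one snapshot, in bits.

    Raises
    ------
    ValueError
        ``"degenerate curvature field"`` when all curvature values coincide
        (a point mass has no differential entropy).
    """
    values = c.values if isinstance(c, CurvatureField) else np.asarray(c, dtype=float)
    if values.size < 2 or np.all(values == values.flat[0]):
        raise ValueError("degenerate curvature field: need >= 2 distinct curvature values")
    est = estimate_density(values, density_config)
    return differential_entropy_bits(est)


@dataclass
class EntropyTrace:
    """Entropy (mean and 95% CI band) along a sweep or time axis."""

    sweep: np.ndarray
    mean_entropy: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    realizations: int

    def __post_init__(self) -> None:
        self.sweep = np.asarray(self.sweep, dtype=float)
        self.mean_entropy = np.asarray(self.mean_entropy, dtype=float)
        self.ci_low = np.asarray(self.ci_low, dtype=float)
        self.ci_high = np.asarray(self.ci_high, dtype=float)
        n = len(self.sweep)
        for arr in (self.mean_entropy, self.ci_low, self.ci_high):
            if len(arr) != n:
                raise ValueError("trace arrays must share one length")
        if len(self.sweep) > 1 and not np.all(np.diff(self.sweep) > 0):
            raise ValueError("sweep labels must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sweep)

    def band_half_width(self) -> np.ndarray:
        return (self.ci_high - self.ci_low) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sweep_label": self.sweep,
                "mean_entropy": self.mean_entropy,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "realizations": self.realizations,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EntropyTrace":
        df = pd.read_csv(path)
        required = {"sweep_label", "mean_entropy", "ci_low", "ci_high", "realizations"}
        if not required.issubset(df.columns):
            raise ValueError(f"malformed trace CSV: columns {sorted(required)} required")
        return cls(
            sweep=df["sweep_label"].to_numpy(),
            mean_entropy=df["mean_entropy"].to_numpy(),
            ci_low=df["ci_low"].to_numpy(),
            ci_high=df["ci_high"].to_numpy(),
            realizations=int(df["realizations"].iloc[0]),
        )


def realization_seed(root_seed: int, value_index: int, realization_index: int) -> int:
    """Deterministic 31-bit child seed for one (sweep value, realization)."""
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(value_index, realization_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def trace_from_realizations(labels: Sequence[float], entropies: np.ndarray) -> EntropyTrace:
    """Fold an (R, T) matrix of per-realization entropies into a trace."""
    h = np.asarray(entropies, dtype=float)
    if h.ndim != 2:
        raise ValueError("entropies must be an (R, T) matrix")
    r = h.shape[0]
    mean = h.mean(axis=0)
    if r > 1:
        half = _CI_Z * h.std(axis=0, ddof=1) / np.sqrt(r)
    else:
        half = np.zeros_like(mean)
    return EntropyTrace(
        sweep=np.asarray(labels, dtype=float),
        mean_entropy=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        realizations=r,
    )


def entropy_sweep(
    graph_factory: Callable[[float, int], WeightedGraph],
    sweep_values: Sequence[float],
    realizations: int,
    seed: int,
    density_config: DensityConfig | None = None,
) -> EntropyTrace:
    """Monte-Carlo entropy trace over a parameter sweep.

    Parameters
    ----------
    graph_factory
        Callable ``(sweep_value, child_seed) -> WeightedGraph`` generating
        one independent snapshot.
    sweep_values
        Strictly increasing parameter grid.
    realizations
        Number R (>= 2) of independent snapshots per sweep value.
    seed
        Root seed; children are split per (value, realization) index.
    """
    if realizations < 2:
        raise ValueError("realizations must be >= 2")
    values = np.asarray(sweep_values, dtype=float)
    h = np.empty((realizations, len(values)))
    for vi, value in enumerate(values.tolist()):
        for ri in range(realizations):
            child = realization_seed(seed, vi, ri)
            try:
                g = graph_factory(float(value), child)
                h[ri, vi] = network_entropy(forman_ricci_all(g), density_config)
            except Exception as exc:
                raise RuntimeError(f"generator failed at sweep value {value!r}: {exc}") from exc
    return trace_from_realizations(values, h)


def entropy_over_sequence(
    seq: SnapshotSequence, density_config: DensityConfig | None = None
) -> np.ndarray:
    """Per-snapshot network entropy of an observed/generated sequence."""
    return np.array(
        [network_entropy(forman_ricci_all(g), density_config) for g in seq.graphs]
    )
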