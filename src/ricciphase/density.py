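"""Nonparametric density estimation for curvature samples.

The primary estimator is a linear (non-thresholded) wavelet series: samples
are affinely rescaled to [0, 1], the scaling coefficients
``f_{j,n} = (1/N) sum_i phi_{j,n}(x_i)`` and wavelet (detail) coefficients
``f~_{s,n} = (1/N) sum_i psi_{s,n}(x_i)`` for ``s = j .. j1`` are formed as
sample means of the dilated/translated basis functions, and the truncated
series is evaluated on a uniform grid.  Because a truncated orthogonal
series can go negative, the raw estimate is clipped at zero and
renormalized to unit mass, then reported back on the original sample scale
with the Jacobian of the affine map applied.

The default family is Daubechies db4; the finest level follows the standard
bias–variance rule ``j1 = max(0, floor(log2(N)/2) - 1)``.  A normalized
histogram on the same grid convention is provided as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
import json
import math

import numpy as np
import pywt

__all__ = ["DensityConfig", "DensityEstimate", "estimate_density", "histogram_density"]


@dataclass(frozen=True)
class DensityConfig:
    """Configuration of the wavelet density estimator.

    Attributes
    ----------
    wavelet_family : str
        PyWavelets family name (default ``"db4"``).
    level_coarse : int
        Coarse scaling level ``j`` (default 0).
    level_fine : int or None
        Finest detail level ``j1``; ``None`` selects
        ``max(level_coarse, floor(log2(N)/2) - 1)`` from the sample count.
    grid_size : int
        Number of uniformly spaced evaluation abscissae (default 1024).
    padding_fraction : float
        Fraction of the sample range added on each side of the grid so the
        compactly supported basis is not truncated at the data boundary.
    """

    wavelet_family: str = "db4"
    level_coarse: int = 0
    level_fine: int | None = None
    grid_size: int = 1024
    padding_fraction: float = 0.05

    def resolved_level_fine(self, n_samples: int) -> int:
        if self.level_fine is not None:
            if self.level_fine < self.level_coarse:
                raise ValueError("level_fine must be >= level_coarse")
            return self.level_fine
        auto = max(0, math.floor(math.log2(n_samples) / 2) - 1)
        return max(self.level_coarse, auto)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DensityConfig":
        return cls(**json.loads(text))


@dataclass
class DensityEstimate:
    """Estimated PDF on a uniform grid, with the estimator configuration."""

    grid: np.ndarray
    values: np.ndarray
    config: DensityConfig
    sample_count: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid/values shape mismatch")

    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.grid))

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Linear interpolation of the density (0 outside the grid)."""
        return np.interp(np.asarray(x, dtype=float), self.grid, self.values, left=0.0, right=0.0)


@lru_cache(maxsize=8)
def _wavelet_tables(family: str):
    """Sampled scaling/wavelet functions of a compactly supported family."""
    wavelet = pywt.Wavelet(family)
    phi, psi, x = wavelet.wavefun(level=12)
    support = wavelet.dec_len - 1  # db-p support is [0, 2p-1]
    return np.asarray(x), np.asarray(phi), np.asarray(psi), support


def _level_coefficients(y: np.ndarray, level: int, table_x, table_f, support: int) -> np.ndarray:
    """Sample-mean coefficients ``(1/N) sum_i f_{level,n}(y_i)`` for all
    translates ``n`` in ``[-support, 2**level]``.

    Exploits compact support: each sample touches at most ``support``
    consecutive translates, so the scatter is a handful of ``bincount``
    passes instead of a dense basis matrix.
    """
    t = np.ldexp(y, level)  # 2^level * y
    base = np.floor(t).astype(np.int64)
    frac = t - base
    num_n = (1 << level) + support + 1
    coeff = np.zeros(num_n)
    for d in range(support):
        vals = np.interp(frac + d, table_x, table_f, left=0.0, right=0.0)
        idx = base - d + support  # n = base - d, shifted so n = -support is slot 0
        coeff += np.bincount(idx, weights=vals, minlength=num_n)[:num_n]
    return coeff * (2.0 ** (level / 2.0) / len(y))


def _accumulate_series(out: np.ndarray, grid: np.ndarray, coeff: np.ndarray,
                       level: int, table_x, table_f, support: int) -> None:
    """Add ``sum_n coeff_n f_{level,n}(grid)`` to ``out`` in place."""
    t = np.ldexp(grid, level)
    base = np.floor(t).astype(np.int64)
    frac = t - base
    scale = 2.0 ** (level / 2.0)
    n_hi = 1 << level
    for d in range(support):
        n = base - d
        valid = (n >= -support) & (n <= n_hi)
        idx = np.clip(n + support, 0, len(coeff) - 1)
        vals = np.interp(frac + d, table_x, table_f, left=0.0, right=0.0)
        out += np.where(valid, coeff[idx], 0.0) * vals * scale


def estimate_density(samples, config: DensityConfig | None = None) -> DensityEstimate:
    """Wavelet series estimate of the PDF underlying ``samples``.

    Raises
    ------
    ValueError
        ``"degenerate sample"`` when all samples coincide (a point mass has
        no density), or fewer than 2 samples are supplied.
    """
    config = config or DensityConfig()
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("degenerate sample: need at least 2 samples")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("degenerate sample: all samples identical")

    span = hi - lo
    y = (x - lo) / span  # rescaled samples in [0, 1]
    j0 = config.level_coarse
    j1 = config.resolved_level_fine(x.size)

    table_x, phi, psi, support = _wavelet_tables(config.wavelet_family)
    pad = config.padding_fraction
    y_grid = np.linspace(-pad, 1.0 + pad, config.grid_size)

    density = np.zeros_like(y_grid)
    # scaling term at the coarse level
    coeff = _level_coefficients(y, j0, table_x, phi, support)
    _accumulate_series(density, y_grid, coeff, j0, table_x, phi, support)
    # detail terms for levels j0 .. j1
    for s in range(j0, j1 + 1):
        coeff = _level_coefficients(y, s, table_x, psi, support)
        _accumulate_series(density, y_grid, coeff, s, table_x, psi, support)

    density = np.clip(density, 0.0, None)
    mass = np.trapezoid(density, y_grid)
    if mass <= 0:
        raise ValueError("degenerate sample: estimated density has no mass")
    density /= mass

    # back to the original scale (Jacobian of y = (x - lo)/span)
    grid = lo + y_grid * span
    values = density / span
    resolved = replace(config, level_fine=j1)
    return DensityEstimate(grid=grid, values=values, config=resolved, sample_count=x.size)


def histogram_density(samples, bin_count: int, config: DensityConfig | None = None) -> DensityEstimate:
    """Normalized histogram evaluated on the same padded-grid convention.

    Serves as a model-free cross-check of the wavelet estimate; the step
    function is sampled on the uniform grid and renormalized to unit
    trapezoid mass.
    """
    config = config or DensityConfig()
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("need at least 1 sample")
    if bin_count < 1:
        raise ValueError("bin_count must be >= 1")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:  # single-valued sample: center a unit-width support on it
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(x, bins=bin_count, range=(lo, hi), density=True)
    span = hi - lo
    pad = config.padding_fraction * span
    grid = np.linspace(lo - pad, hi + pad, config.grid_size)
    idx = np.clip(np.searchsorted(edges, grid, side="right") - 1, 0, bin_count - 1)
    values = np.where((grid >= lo) & (grid <= hi), counts[idx], 0.0)
    mass = np.trapezoid(values, grid)
    if mass > 0:
        values = values / mass
    return DensityEstimate(grid=grid, values=values, config=config, sample_count=x.size)
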