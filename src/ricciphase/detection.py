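"""Transition-boundary quantification and change-point detection.

A phase transition along a sweep shows up as a unimodal bump in the first
derivative of the entropy trace.  Given a threshold gamma, the admissible
set is ``I = { alpha : |dH/dalpha| <= gamma }``; the transition boundaries
are the admissible grid points immediately flanking the derivative peak:
the largest admissible ``alpha`` at or below the peak (lower boundary) and
the smallest admissible ``alpha`` at or above it (upper boundary).  The
default gamma is one fifth of the derivative peak.

For time-labelled sequences, change points are the steps whose entropy jump
``|H(G_t) - H(G_{t-1})|`` exceeds a threshold; the default threshold is a
robust null scale (5x the median absolute successive difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy import stats

from .entropy import EntropyTrace, trace_from_realizations

__all__ = [
    "NoTransitionError",
    "BoundaryNotFoundError",
    "TransitionReport",
    "SlopeScaling",
    "first_derivative",
    "default_gamma",
    "transition_boundaries",
    "detect_change_points",
    "rise_slope",
    "slope_scaling_fit",
]


class NoTransitionError(RuntimeError):
    """The derivative never exceeds the threshold: no transition detected."""


class BoundaryNotFoundError(RuntimeError):
    """The admissible set is empty on one side of the derivative peak."""


@dataclass
class TransitionReport:
    """Outcome of the boundary rule on one derivative trace."""

    gamma: float
    admissible_set: np.ndarray
    boundary_low: float
    boundary_high: float
    peak_location: float
    peak_value: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "gamma": self.gamma,
                "alpha1": self.boundary_low,
                "alpha2": self.boundary_high,
                "peak_location": self.peak_location,
                "peak_value": self.peak_value,
            }
        )


@dataclass
class SlopeScaling:
    """Fitted growth of the transition slope a_N with network size N.

    ``delta`` is the exponent of the power-of-log model
    ``a_N = c (log N)^delta``; ``linear_slope`` is the slope of the plain
    ``a_N`` vs ``log N`` regression reported for comparison.
    """

    sizes: np.ndarray
    slopes: np.ndarray
    delta: float
    delta_stderr: float
    linear_slope: float
    linear_intercept: float
    linear_r: float


def first_derivative(
    trace: EntropyTrace, log_labels: bool = False, smooth_window: int | None = None
) -> EntropyTrace:
    """First derivative of the mean entropy along the sweep axis.

    Second-order central differences at interior points and one-sided
    differences at the ends (``numpy.gradient``); exact for quadratics.
    With ``log_labels=True`` the derivative is taken with respect to
    ``ln(label)`` (for log-spaced sweeps), while the label axis itself is
    left unchanged.  ``smooth_window`` (odd, e.g. 3) applies an optional
    moving average to the mean trace before differencing; the default is
    the raw trace.
    """
    if len(trace) < 3:
        raise ValueError("need at least 3 sweep points for a derivative")
    axis = np.log(trace.sweep) if log_labels else trace.sweep
    if not np.all(np.diff(axis) > 0):
        raise ValueError("sweep labels must be strictly increasing")
    h = trace.mean_entropy
    if smooth_window is not None:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        pad = smooth_window // 2
        padded = np.concatenate([h[:1].repeat(pad), h, h[-1:].repeat(pad)])
        h = np.convolve(padded, np.ones(smooth_window) / smooth_window, mode="valid")
    d = np.gradient(h, axis)
    return EntropyTrace(
        sweep=trace.sweep,
        mean_entropy=d,
        ci_low=d,
        ci_high=d,
        realizations=trace.realizations,
    )


def default_gamma(deriv_trace: EntropyTrace, fraction: float = 0.2) -> float:
    """Threshold gamma_N as a fraction (default 1/5) of the derivative peak."""
    if len(deriv_trace) == 0:
        raise ValueError("empty derivative trace")
    return fraction * float(np.max(np.abs(deriv_trace.mean_entropy)))


def transition_boundaries(deriv_trace: EntropyTrace, gamma: float) -> TransitionReport:
    """Apply the admissible-interval boundary rule to a derivative trace.

    The pivot between the lower and upper search ranges is the global peak
    of ``|dH/dalpha|`` (for the growing-network sweep the peak sits at the
    critical exponent 1, recovering the printed boundaries).

    Raises
    ------
    NoTransitionError
        If the peak does not exceed ``gamma``.
    BoundaryNotFoundError
        If no admissible grid point exists on one side of the peak.
    """
    if len(deriv_trace) == 0:
        raise ValueError("empty derivative trace")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    alpha = deriv_trace.sweep
    mag = np.abs(deriv_trace.mean_entropy)
    peak_idx = int(np.argmax(mag))
    peak_value = float(mag[peak_idx])
    if peak_value <= gamma:
        raise NoTransitionError("no transition detected: derivative peak <= gamma")
    admissible = mag <= gamma
    left = np.flatnonzero(admissible[: peak_idx + 1])
    right = np.flatnonzero(admissible[peak_idx:]) + peak_idx
    if len(left) == 0:
        raise BoundaryNotFoundError("boundary not found below the derivative peak")
    if len(right) == 0:
        raise BoundaryNotFoundError("boundary not found above the derivative peak")
    return TransitionReport(
        gamma=float(gamma),
        admissible_set=alpha[admissible],
        boundary_low=float(alpha[left[-1]]),
        boundary_high=float(alpha[right[0]]),
        peak_location=float(alpha[peak_idx]),
        peak_value=peak_value,
    )


def detect_change_points(time_trace: EntropyTrace, jump_threshold: float | None = None) -> list[float]:
    """Time labels where the successive entropy jump exceeds the threshold.

    The effective threshold is ``max(jump_threshold, 5 * median |dH|)``
    so a user floor never drops below the robust null scale of the trace;
    with no user value the robust scale alone is used.
    """
    if len(time_trace) < 2:
        raise ValueError("need at least 2 time points")
    jumps = np.abs(np.diff(time_trace.mean_entropy))
    robust = 5.0 * float(np.median(jumps))
    if jump_threshold is None:
        threshold = robust
    else:
        if jump_threshold <= 0:
            raise ValueError("jump_threshold must be > 0")
        threshold = max(float(jump_threshold), robust)
    hits = np.flatnonzero(jumps > threshold) + 1
    return [float(time_trace.sweep[i]) for i in hits]


def rise_slope(trace: EntropyTrace, log_labels: bool = False) -> float:
    """Slope a_N of the entropy rise at the transition.

    The tangent slope at the derivative-peak sweep value, i.e. the maximum
    of the first derivative of the mean trace.

    Raises
    ------
    NoTransitionError
        If the trace is flat (zero derivative everywhere).
    """
    deriv = first_derivative(trace, log_labels=log_labels)
    mag = np.abs(deriv.mean_entropy)
    if float(np.max(mag)) == 0.0:
        raise NoTransitionError("no transition detected: flat trace")
    return float(deriv.mean_entropy[int(np.argmax(mag))])


def slope_scaling_fit(pairs) -> SlopeScaling:
    """Fit the growth of the rise slope a_N against network size N.

    Least squares of ``log a_N`` on ``log log N`` gives the exponent delta
    of ``a_N = c (log N)^delta`` with its standard error; the plain linear
    regression of ``a_N`` on ``log N`` is reported alongside.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (N, a_N) pairs")
    sizes, slopes = arr[:, 0], arr[:, 1]
    if len(np.unique(sizes)) != len(sizes):
        raise ValueError("duplicate network sizes")
    if np.any(sizes <= 1):
        raise ValueError("network sizes must exceed 1")
    if np.any(slopes <= 0):
        raise ValueError("rise slopes must be positive")
    power_fit = stats.linregress(np.log(np.log(sizes)), np.log(slopes))
    linear_fit = stats.linregress(np.log(sizes), slopes)
    return SlopeScaling(
        sizes=sizes,
        slopes=slopes,
        delta=float(power_fit.slope),
        delta_stderr=float(power_fit.stderr),
        linear_slope=float(linear_fit.slope),
        linear_intercept=float(linear_fit.intercept),
        linear_r=float(linear_fit.rvalue),
    )
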