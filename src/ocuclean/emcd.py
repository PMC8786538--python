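"""Empirical Mean Curve Decomposition (EMCD) and its inverse.

EMCD is a data-driven multiscale decomposition in the spirit of empirical
mode decomposition: cubic B-spline envelopes are fitted through the local
maxima (superior envelope) and minima (inferior envelope) of the signal, and
their average — the *mean curve* — captures the local trend.  Subtracting the
mean curve leaves an oscillatory *mode*; iterating on the mean curve itself
extracts progressively smoother trends.  After K levels the signal is exactly
the sum of the K modes plus the final *leftover* trend, so reconstruction
(the inverse) is plain summation and conservation holds to machine precision.

The empirical-waveform (EWF) statistics summarize how oscillatory a series
is: the mode count ``md`` is the average of the numbers of maxima and minima
(one full sine cycle contributes exactly one), the empirical period is
``T / md`` samples and the empirical frequency its reciprocal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline

__all__ = [
    "ExtremaSeries",
    "EMCDResult",
    "EWFStats",
    "NeedsExtremaError",
    "find_extrema",
    "envelope",
    "mean_curve",
    "ewf_stats",
    "emcd_decompose",
    "inverse_emcd",
    "plot_decomposition",
]

DEFAULT_MAX_LEVELS = 5
MIN_SIGNAL_LENGTH = 8


class NeedsExtremaError(ValueError):
    """Raised when an envelope is requested with fewer than two extrema."""


@dataclass
class ExtremaSeries:
    maxima: list[tuple[int, float]]
    minima: list[tuple[int, float]]

    @property
    def n_maxima(self) -> int:
        return len(self.maxima)

    @property
    def n_minima(self) -> int:
        return len(self.minima)


@dataclass
class EMCDResult:
    modes: list[np.ndarray]
    leftover: np.ndarray
    n_levels: int

    def reconstruct(self) -> np.ndarray:
        return inverse_emcd(self.modes, self.leftover)


@dataclass
class EWFStats:
    mode_count: float
    empirical_period: float  # samples; NaN when mode_count == 0
    empirical_frequency: float  # cycles/sample; NaN when mode_count == 0


def find_extrema(signal: np.ndarray) -> ExtremaSeries:
    """Strict interior local extrema; plateaus collapse to their midpoint."""
    x = np.asarray(signal, dtype=float)
    n = x.size
    maxima: list[tuple[int, float]] = []
    minima: list[tuple[int, float]] = []
    if n < 3:
        return ExtremaSeries(maxima, minima)

    # collapse runs of equal values to (midpoint index, value)
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))
    mids = (starts + ends) // 2
    vals = x[starts]
    if len(vals) < 3:
        return ExtremaSeries(maxima, minima)

    rising = np.diff(vals) > 0  # between consecutive runs
    is_max = rising[:-1] & ~rising[1:]
    is_min = ~rising[:-1] & rising[1:]
    for i in np.flatnonzero(is_max) + 1:
        maxima.append((int(mids[i]), float(vals[i])))
    for i in np.flatnonzero(is_min) + 1:
        minima.append((int(mids[i]), float(vals[i])))
    return ExtremaSeries(maxima, minima)


def envelope(
    points: list[tuple[int, float]], length: int, which: str = "superior"
) -> np.ndarray:
    """Cubic B-spline through the extrema, constant-extended beyond the ends.

    ``which`` only labels the request in error messages; superior envelopes
    are fitted through maxima, inferior through minima — the caller supplies
    the matching point list.
    """
    if len(points) < 2:
        raise NeedsExtremaError(
            f"{which} envelope needs >= 2 extrema, got {len(points)} (NEEDS_EXTREMA)"
        )
    idx = np.array([p[0] for p in points], dtype=float)
    val = np.array([p[1] for p in points], dtype=float)
    k = min(3, len(points) - 1)
    spline = make_interp_spline(idx, val, k=k)
    t = np.arange(length, dtype=float)
    inner = np.clip(t, idx[0], idx[-1])
    env = np.asarray(spline(inner), dtype=float)
    # constant extension by the nearest extremum value
    env[t < idx[0]] = val[0]
    env[t > idx[-1]] = val[-1]
    return env


def mean_curve(signal: np.ndarray, extrema: ExtremaSeries | None = None) -> np.ndarray:
    """Average of the superior and inferior envelopes (the local trend)."""
    x = np.asarray(signal, dtype=float)
    ext = extrema if extrema is not None else find_extrema(x)
    sup = envelope(ext.maxima, x.size, "superior")
    inf = envelope(ext.minima, x.size, "inferior")
    return 0.5 * (sup + inf)


def ewf_stats(signal: np.ndarray) -> EWFStats:
    x = np.asarray(signal, dtype=float)
    ext = find_extrema(x)
    md = 0.5 * (ext.n_maxima + ext.n_minima)
    if md > 0:
        return EWFStats(md, x.size / md, md / x.size)
    return EWFStats(0.0, float("nan"), float("nan"))


def emcd_decompose(
    signal: np.ndarray, max_levels: int = DEFAULT_MAX_LEVELS
) -> EMCDResult:
    """Iterated mean-curve extraction.

    Per level: ``mode = current - mean_curve(current)`` and the iteration
    continues on the mean curve; it stops at ``max_levels`` or as soon as the
    current trend has fewer than two maxima or two minima.  The final trend is
    the leftover, so ``sum(modes) + leftover == signal`` identically.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < MIN_SIGNAL_LENGTH:
        raise NeedsExtremaError(
            f"signal length {x.size} below minimum {MIN_SIGNAL_LENGTH}"
        )
    modes: list[np.ndarray] = []
    cur = x
    for _ in range(max_levels):
        ext = find_extrema(cur)
        if ext.n_maxima < 2 or ext.n_minima < 2:
            break
        trend = mean_curve(cur, ext)
        modes.append(cur - trend)
        cur = trend
    return EMCDResult(modes=modes, leftover=cur.copy(), n_levels=len(modes))


def inverse_emcd(modes: list[np.ndarray], leftover: np.ndarray) -> np.ndarray:
    """Reconstruction: elementwise sum of the (possibly restored) mode stack
    and the leftover trend."""
    out = np.array(leftover, dtype=float, copy=True)
    for m in modes:
        out += m
    return out


def plot_decomposition(result: EMCDResult, signal: np.ndarray | None = None, ax=None):
    """Overlay plot of modes and leftover (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if signal is not None:
        ax.plot(signal, color="0.7", label="input")
    for i, m in enumerate(result.modes):
        ax.plot(m, label=f"mode {i}")
    ax.plot(result.leftover, "k--", label="leftover")
    ax.legend(loc="upper right", fontsize="small")
    return ax
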