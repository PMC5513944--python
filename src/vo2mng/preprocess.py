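"""Breath-to-grid interpolation, filtering and ensemble averaging.

The raw breath-by-breath record is linearly interpolated onto the 1-s
grid; optional moving-average (3/5/7 s) or zero-phase Butterworth
low-pass (0.075 Hz cutoff) filtering can then be applied, and repeated
PRBS responses are combined by pointwise ensemble averaging.  All of
these operators are linear.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .series import BreathSeries, UniformSeries

__all__ = [
    "BreathSeries",
    "UniformSeries",
    "interpolate_1s",
    "moving_average",
    "lowpass",
    "ensemble_average",
]

DEFAULT_LOWPASS_HZ = 0.075


def interpolate_1s(
    breaths: BreathSeries,
    grid_start: float | None = None,
    grid_end: float | None = None,
    dt: float = 1.0,
) -> UniformSeries:
    """Linear interpolation of a breath record onto the second-by-second grid.

    Parameters
    ----------
    breaths : BreathSeries
        At least two breaths.
    grid_start, grid_end : float, optional
        Grid limits (s).  Default to the smallest/largest integer-second
        times inside the breath support.  Extrapolation is refused.
    dt : float
        Grid spacing (s); 1 s by convention.
    """
    if breaths.n < 2:
        raise ValueError("need at least two breaths to interpolate")
    first, last = breaths.times[0], breaths.times[-1]
    if grid_start is None:
        grid_start = math.ceil(first / dt) * dt
    if grid_end is None:
        grid_end = math.floor(last / dt) * dt
    if grid_start < first - 1e-9 or grid_end > last + 1e-9:
        raise ValueError(
            f"grid [{grid_start}, {grid_end}] s extends beyond the breath support "
            f"[{first}, {last}] s; extrapolation is not performed"
        )
    if grid_end < grid_start:
        raise ValueError("grid_end must not precede grid_start")
    n = int(round((grid_end - grid_start) / dt)) + 1
    grid = grid_start + np.arange(n) * dt
    values = np.interp(grid, breaths.times, breaths.vo2)
    return UniformSeries(t0=float(grid_start), dt=dt, values=values)


def moving_average(series: UniformSeries, window: int) -> UniformSeries:
    """Centered running mean over an odd window of ``window`` samples.

    The window is truncated at the series edges (mean over the samples
    actually available), so the output has the same length and grid as
    the input.  ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive sample count, got {window}")
    if window == 1:
        return series
    kernel = np.ones(window)
    num = np.convolve(series.values, kernel, mode="same")
    den = np.convolve(np.ones(series.n), kernel, mode="same")
    return UniformSeries(t0=series.t0, dt=series.dt, values=num / den)


def lowpass(
    series: UniformSeries,
    cutoff_hz: float = DEFAULT_LOWPASS_HZ,
    order: int = 4,
) -> UniformSeries:
    """Zero-phase Butterworth low-pass filter.

    A forward-backward (``filtfilt``) pass of an ``order``-th Butterworth
    filter, preserving timing information for both analysis branches.
    """
    nyquist = 0.5 / series.dt
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie strictly between 0 and the Nyquist "
            f"frequency {nyquist} Hz"
        )
    b, a = butter(order, cutoff_hz, btype="low", fs=1.0 / series.dt)
    return UniformSeries(t0=series.t0, dt=series.dt, values=filtfilt(b, a, series.values))


def ensemble_average(replicates: Sequence[UniformSeries]) -> UniformSeries:
    """Pointwise mean of time-aligned replicate responses.

    All replicates must share ``t0``, ``dt`` and length; alignment across
    repetitions is the caller's responsibility (the pipeline generates
    replicates on a common grid by construction).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    ref = replicates[0]
    for i, rep in enumerate(replicates[1:], start=2):
        if not ref.same_grid(rep):
            raise ValueError(
                f"replicate {i} is not aligned with replicate 1 "
                f"(t0={rep.t0} vs {ref.t0}, dt={rep.dt} vs {ref.dt}, "
                f"n={rep.n} vs {ref.n}); ensemble averaging requires a shared grid"
            )
    stacked = np.vstack([rep.values for rep in replicates])
    return UniformSeries(t0=ref.t0, dt=ref.dt, values=stacked.mean(axis=0))
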