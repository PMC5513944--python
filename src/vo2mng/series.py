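"""Core time-series containers shared across the analysis pipeline.

Three containers cover the data flow of a PRBS exercise test:

* :class:`WorkRateSeries` — the two-level work-rate input delivered by the
  ergometer, uniformly sampled.
* :class:`BreathSeries` — raw breath-by-breath oxygen uptake, irregularly
  sampled at breath end-times.
* :class:`UniformSeries` — the second-by-second V̇O2 signal that both the
  frequency-domain and the time-domain analyses operate on.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WorkRateSeries", "UniformSeries", "BreathSeries"]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class WorkRateSeries:
    """Two-level work-rate protocol Ẇ(t) on a uniform time grid.

    Parameters
    ----------
    dt : float
        Sampling interval in seconds.
    values : array-like
        Work rate per sample in watts; every sample must equal ``low`` or
        ``high``.
    n_periods : int
        Number of concatenated PRBS periods contained in ``values``.
    low, high : float
        The two work-rate levels in watts (e.g. 25 and 100 W).
    """

    dt: float
    values: np.ndarray
    n_periods: int = 1
    low: float = 25.0
    high: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_float_array(self.values, "values"))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.low >= self.high:
            raise ValueError("low work-rate level must be below the high level")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if self.values.size % self.n_periods != 0:
            raise ValueError("series length is not divisible by n_periods")
        levels = np.unique(self.values)
        if not np.all(np.isin(levels, [self.low, self.high])):
            raise ValueError(
                f"work-rate samples must equal low={self.low} W or high={self.high} W; "
                f"found levels {levels}"
            )

    @property
    def period_samples(self) -> int:
        return self.values.size // self.n_periods

    @property
    def period_s(self) -> float:
        return self.period_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    def one_period(self) -> np.ndarray:
        """Work-rate samples of the first period."""
        return self.values[: self.period_samples].copy()

    def to_uniform(self) -> "UniformSeries":
        """View the first period as a :class:`UniformSeries` (units: W)."""
        return UniformSeries(t0=0.0, dt=self.dt, values=self.one_period())


@dataclass(frozen=True)
class UniformSeries:
    """Uniformly sampled signal, by convention second-by-second V̇O2.

    Parameters
    ----------
    t0 : float
        Time of the first sample (s).
    dt : float
        Sample spacing (s); 1 s throughout the standard pipeline.
    values : array-like
        Signal samples (ml·min⁻¹ for V̇O2, W for work rate).
    """

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_float_array(self.values, "values"))
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.dt

    @property
    def duration(self) -> float:
        return self.n * self.dt

    def same_grid(self, other: "UniformSeries", tol: float = 1e-9) -> bool:
        return (
            abs(self.t0 - other.t0) <= tol
            and abs(self.dt - other.dt) <= tol
            and self.n == other.n
        )


@dataclass(frozen=True)
class BreathSeries:
    """Irregular breath-by-breath V̇O2 record.

    ``times`` are breath end-timestamps in seconds (strictly increasing);
    ``vo2`` is per-breath oxygen uptake in ml·min⁻¹ (finite, non-negative).
    """

    times: np.ndarray
    vo2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _as_float_array(self.times, "times"))
        object.__setattr__(self, "vo2", _as_float_array(self.vo2, "vo2"))
        if self.times.size != self.vo2.size:
            raise ValueError("times and vo2 must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("breath timestamps must be strictly increasing")
        if np.any(self.vo2 < 0):
            raise ValueError("vo2 must be non-negative")

    @property
    def n(self) -> int:
        return self.times.size
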