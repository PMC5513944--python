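"""Synthetic V̇O2 data: first-order responses to PRBS input plus a
breath-by-breath measurement model.

The aerobic response to moderate-intensity work-rate changes is modelled
as a first-order linear system

    τ · dy/dt = a0 + G · (u(t − td) − u_low) − y,      G = a1 / (high − low)

so that the steady-state output is ``a0`` at the low work-rate level and
``a0 + a1`` at the high level.  The discrete update uses the exact
zero-order-hold solution (piecewise exponential between input switches),
so the only difference from the continuous-time system is the sampling
itself.  The simulation runs warm-up periods before the period that is
returned, mirroring the practice of discarding the first PRBS of a
session as a warm-up.

The breath sampler turns the continuous-valued second-by-second signal
into an irregular breath-by-breath record with white Gaussian
breath-to-breath noise — the standard description of V̇O2 measurement
fluctuation at the mouth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .series import BreathSeries, UniformSeries, WorkRateSeries

__all__ = [
    "FirstOrderParams",
    "TABLE_SIMULATIONS",
    "EXTREME_TAUS",
    "EXTREME_H_RANGES",
    "first_order_response",
    "breath_sample",
    "run_table2_study",
    "run_extreme_tau_study",
]


@dataclass(frozen=True)
class FirstOrderParams:
    """Parameters of the first-order V̇O2 model.

    Parameters
    ----------
    a0 : float
        Baseline V̇O2 at the low work-rate level (ml·min⁻¹).
    a1 : float
        Steady-state amplitude from the low to the high level (ml·min⁻¹).
    tau_s : float
        Time constant (s).
    td : float
        Pure delay (s); defaults to 0, matching the muscular response
        which is expected to show no circulatory transit delay.
    """

    a0: float
    a1: float
    tau_s: float
    td: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.a1 < 0:
            raise ValueError("a1 must be non-negative")
        if self.td < 0:
            raise ValueError("td must be non-negative")


#: The ten (a0, a1, tau_s) parameter sets of the in-silico study.
TABLE_SIMULATIONS: tuple[FirstOrderParams, ...] = (
    FirstOrderParams(300.0, 700.0, 15.0),
    FirstOrderParams(400.0, 800.0, 45.0),
    FirstOrderParams(350.0, 750.0, 25.0),
    FirstOrderParams(250.0, 900.0, 21.0),
    FirstOrderParams(200.0, 750.0, 39.0),
    FirstOrderParams(150.0, 600.0, 52.0),
    FirstOrderParams(125.0, 800.0, 42.0),
    FirstOrderParams(350.0, 600.0, 35.0),
    FirstOrderParams(250.0, 750.0, 48.0),
    FirstOrderParams(330.0, 650.0, 19.0),
)

#: Time constants of the extreme-τ study (s).
EXTREME_TAUS: tuple[float, ...] = (0.001, 0.1, 1.0, 5.0, 15.0, 35.0, 80.0, 200.0, 500.0, 1500.0)

#: Harmonic ranges compared in the extreme-τ study (inclusive lo..hi).
EXTREME_H_RANGES: tuple[tuple[int, int], ...] = ((2, 3), (2, 4), (2, 5), (2, 10))

# Relative tolerance for the warm-up periodicity check: the returned period
# must match the preceding one to this accuracy or warm-up is doubled.
_PERIODICITY_RTOL = 1e-6
_MAX_WARMUP_PERIODS = 512


def _simulate_periods(
    period_values: np.ndarray,
    params: FirstOrderParams,
    dt: float,
    low: float,
    high: float,
    n_total_periods: int,
) -> np.ndarray:
    """Exact zero-order-hold first-order response over n_total_periods."""
    gain = params.a1 / (high - low)
    u = np.tile(period_values, n_total_periods)
    n = u.size

    # Delay by td = q*dt + r splits each sampling interval into (at most)
    # two constant-input segments; both are propagated exactly.
    q, r = divmod(params.td, dt)
    q = int(round(q))
    if abs(r - dt) < 1e-12:  # td is an exact multiple of dt
        q, r = q + 1, 0.0

    def delayed(shift: int) -> np.ndarray:
        # input before t=0 is held at its first value
        if shift <= 0:
            return u
        return np.concatenate([np.full(shift, u[0]), u[:-shift]])

    tau = params.tau_s
    target_b = params.a0 + gain * (delayed(q) - low)       # active on [k+r, k+1)
    target_a = params.a0 + gain * (delayed(q + 1) - low)   # active on [k, k+r)
    alpha1 = np.exp(-r / tau)
    alpha2 = np.exp(-(dt - r) / tau)
    decay = alpha1 * alpha2  # = exp(-dt/tau)
    forced = alpha2 * (1.0 - alpha1) * target_a + (1.0 - alpha2) * target_b

    y0 = params.a0  # start at low-level steady state; warm-up removes any transient
    # recursion y[k+1] = decay*y[k] + forced[k]
    out, _ = lfilter([1.0], [1.0, -decay], forced, zi=[decay * y0])
    return np.concatenate([[y0], out[:-1]])


def first_order_response(
    protocol: WorkRateSeries,
    params: FirstOrderParams,
    n_warmup_periods: int = 2,
) -> UniformSeries:
    """Simulate the first-order V̇O2 response and return the final period.

    The system is driven by ``n_warmup_periods + 1`` repetitions of the
    protocol period and only the last period is returned, so the output is
    the periodic steady-state response.  For very slow systems the warm-up
    is extended automatically until consecutive periods agree to a relative
    tolerance of 1e-6.

    Parameters
    ----------
    protocol : WorkRateSeries
        The PRBS input; only its first period is used as the repeating unit.
    params : FirstOrderParams
        Model parameters.
    n_warmup_periods : int
        Minimum number of discarded periods (≥ 1).
    """
    if n_warmup_periods < 1:
        raise ValueError("n_warmup_periods must be >= 1")
    period = protocol.one_period()
    n = period.size
    warmup = n_warmup_periods
    while True:
        y = _simulate_periods(
            period, params, protocol.dt, protocol.low, protocol.high, warmup + 1
        )
        last, prev = y[-n:], y[-2 * n : -n]
        scale = max(1.0, float(np.max(np.abs(last))))
        if np.max(np.abs(last - prev)) <= _PERIODICITY_RTOL * scale:
            break
        if warmup >= _MAX_WARMUP_PERIODS:  # pragma: no cover - defensive cap
            break
        warmup *= 2
    return UniformSeries(t0=0.0, dt=protocol.dt, values=last)


def breath_sample(
    signal: UniformSeries,
    mean_breath_interval: float = 3.0,
    interval_jitter: float = 0.2,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence | None = 0,
) -> BreathSeries:
    """Sample a uniform signal at irregular breath times with additive noise.

    Breath intervals are drawn from a lognormal distribution with the given
    mean and coefficient of variation (``interval_jitter``); per-breath V̇O2
    is the linearly interpolated signal value plus i.i.d. Gaussian noise of
    standard deviation ``noise_sd`` (ml·min⁻¹), independent of signal level.

    Output is fully reproducible for a fixed ``seed``.
    """
    if signal.n == 0:
        raise ValueError("cannot breath-sample an empty signal")
    if mean_breath_interval <= 0:
        raise ValueError("mean_breath_interval must be positive")
    if interval_jitter < 0:
        raise ValueError("interval_jitter must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    t_start, t_end = signal.t0, signal.t0 + (signal.n - 1) * signal.dt
    times = [t_start]
    if interval_jitter > 0:
        sigma2 = np.log1p(interval_jitter**2)
        mu = np.log(mean_breath_interval) - sigma2 / 2.0
        sigma = np.sqrt(sigma2)
    while times[-1] < t_end:
        if interval_jitter > 0:
            interval = rng.lognormal(mean=mu, sigma=sigma)
        else:
            interval = mean_breath_interval
        times.append(min(times[-1] + interval, t_end))
    times = np.asarray(times)
    vo2 = np.interp(times, signal.times, signal.values)
    if noise_sd > 0:
        vo2 = vo2 + rng.normal(0.0, noise_sd, size=vo2.size)
    return BreathSeries(times=times, vo2=np.maximum(vo2, 0.0))


def run_table2_study(h_range: tuple[int, int] = (2, 4)) -> pd.DataFrame:
    """Noiseless simulation study over the ten printed parameter sets.

    For each (a0, a1, tau_s) the full pipeline — PRBS generation, exact
    first-order simulation with warm-up, 1-s sampling, harmonic
    decomposition — yields the average absolute harmonic gain and the mean
    normalized gain, both over harmonics ``h_range`` (default 2–4).

    Returns
    -------
    pandas.DataFrame
        Columns ``a0, a1, tau_s, mean_gain, mng``, one row per simulation.
    """
    from .freq import gain_profile, harmonic_decomposition, mean_gain
    from .prbs import prbs_protocol

    protocol = prbs_protocol()
    input_dec = harmonic_decomposition(protocol.to_uniform(), n_harmonics=max(4, h_range[1]))
    rows = []
    for params in TABLE_SIMULATIONS:
        response = first_order_response(protocol, params)
        output_dec = harmonic_decomposition(response, n_harmonics=max(4, h_range[1]))
        profile = gain_profile(input_dec, output_dec, h_range=h_range)
        rows.append(
            {
                "a0": params.a0,
                "a1": params.a1,
                "tau_s": params.tau_s,
                "mean_gain": mean_gain(profile, h_range),
                "mng": profile.mng,
            }
        )
    return pd.DataFrame(rows)


def run_extreme_tau_study(
    taus: tuple[float, ...] = EXTREME_TAUS,
    h_ranges: tuple[tuple[int, int], ...] = EXTREME_H_RANGES,
    a0: float = 300.0,
    a1: float = 700.0,
) -> pd.DataFrame:
    """MNG over extreme time constants and several harmonic ranges.

    Fixes the amplitude parameters and sweeps ``tau_s`` over ``taus``,
    computing the pipeline MNG for every harmonic range in ``h_ranges``.
    The result is suitable for sigmoid fitting against log10(τ).

    Returns
    -------
    pandas.DataFrame
        Columns ``tau_s, h_lo, h_hi, mng``.
    """
    from .freq import gain_profile, harmonic_decomposition
    from .prbs import prbs_protocol

    if any(tau <= 0 for tau in taus):
        raise ValueError("all time constants must be positive")
    h_max = max(hi for _, hi in h_ranges)
    protocol = prbs_protocol()
    input_dec = harmonic_decomposition(protocol.to_uniform(), n_harmonics=h_max)
    rows = []
    for tau in taus:
        response = first_order_response(protocol, FirstOrderParams(a0, a1, tau))
        output_dec = harmonic_decomposition(response, n_harmonics=h_max)
        for h_lo, h_hi in h_ranges:
            profile = gain_profile(input_dec, output_dec, h_range=(h_lo, h_hi))
            rows.append({"tau_s": tau, "h_lo": h_lo, "h_hi": h_hi, "mng": profile.mng})
    return pd.DataFrame(rows)
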