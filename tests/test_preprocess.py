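"""Interpolation, filtering and ensemble averaging."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vo2mng import (
    BreathSeries,
    UniformSeries,
    ensemble_average,
    interpolate_1s,
    lowpass,
    moving_average,
)


def _sinusoid(freq_hz, n=450, amp=1.0):
    t = np.arange(n)
    return UniformSeries(t0=0.0, dt=1.0, values=amp * np.sin(2 * np.pi * freq_hz * t))


def _projected_amplitude(series, freq_hz):
    """Amplitude of a sinusoid measured by quadrature projection (oracle)."""
    t = series.times
    c = np.cos(2 * np.pi * freq_hz * t)
    s = np.sin(2 * np.pi * freq_hz * t)
    return 2.0 * np.hypot(series.values @ c, series.values @ s) / t.size


def test_midpoint_interpolation():
    breaths = BreathSeries(times=[0.0, 2.0], vo2=[400.0, 600.0])
    grid = interpolate_1s(breaths, 0.0, 2.0)
    assert grid.values[1] == pytest.approx(500.0)


def test_breaths_on_grid_are_identity():
    times = np.arange(0.0, 10.0)
    vo2 = 500.0 + 50.0 * np.sin(times)
    grid = interpolate_1s(BreathSeries(times=times, vo2=vo2))
    np.testing.assert_allclose(grid.values, vo2)


def test_interpolation_error_bounded_for_smooth_signal():
    """Irregularly sampled exponential: interpolation error is bounded by
    h^2 * max|f''| / 8 with h the largest breath gap."""
    rng = np.random.default_rng(42)
    a, tau = 750.0, 30.0
    f = lambda t: 900.0 + a * (1.0 - np.exp(-t / tau))
    times = np.unique(np.concatenate([[0.0], np.cumsum(rng.uniform(1.0, 5.0, 80))]))
    breaths = BreathSeries(times=times, vo2=f(times))
    grid = interpolate_1s(breaths)
    h = np.max(np.diff(times))
    bound = h**2 * (a / tau**2) / 8.0
    assert np.max(np.abs(grid.values - f(grid.times))) <= bound + 1e-9


def test_interpolation_refuses_extrapolation():
    breaths = BreathSeries(times=[1.5, 5.0], vo2=[400.0, 500.0])
    with pytest.raises(ValueError, match="extrapolation"):
        interpolate_1s(breaths, grid_start=0.0, grid_end=5.0)


@pytest.mark.parametrize("window", [3, 5, 7])
def test_moving_average_preserves_constants_and_length(window):
    series = UniformSeries(t0=0.0, dt=1.0, values=np.full(100, 700.0))
    out = moving_average(series, window)
    assert out.n == 100
    np.testing.assert_allclose(out.values, 700.0)


def test_moving_average_window_one_is_identity():
    series = _sinusoid(0.01)
    assert moving_average(series, 1) is series


def test_moving_average_rejects_even_window():
    with pytest.raises(ValueError, match="odd"):
        moving_average(_sinusoid(0.01), 4)


def test_lowpass_passband_and_stopband_attenuation():
    f_pass = 1.0 / 450.0  # fundamental PRBS frequency, far below cutoff
    f_stop = 0.4
    passband = lowpass(_sinusoid(f_pass, n=4500))
    stopband = lowpass(_sinusoid(f_stop, n=4500))
    assert _projected_amplitude(passband, f_pass) > 0.99
    assert _projected_amplitude(stopband, f_stop) < 0.05


def test_lowpass_leaves_constants_unchanged():
    series = UniformSeries(t0=0.0, dt=1.0, values=np.full(300, 850.0))
    np.testing.assert_allclose(lowpass(series).values, 850.0, rtol=1e-9)


def test_lowpass_rejects_cutoff_at_nyquist():
    with pytest.raises(ValueError, match="Nyquist"):
        lowpass(_sinusoid(0.01), cutoff_hz=0.5)


def test_ensemble_average_pointwise_mean():
    a = UniformSeries(t0=0.0, dt=1.0, values=np.array([1.0, 2.0, 3.0]))
    b = UniformSeries(t0=0.0, dt=1.0, values=np.array([3.0, 2.0, 1.0]))
    np.testing.assert_allclose(ensemble_average([a, b]).values, [2.0, 2.0, 2.0])
    np.testing.assert_allclose(ensemble_average([a, a, a]).values, a.values)


def test_ensemble_average_rejects_misaligned_grids():
    a = UniformSeries(t0=0.0, dt=1.0, values=np.zeros(10))
    b = UniformSeries(t0=5.0, dt=1.0, values=np.zeros(10))
    with pytest.raises(ValueError, match="aligned"):
        ensemble_average([a, b])


def test_ensemble_noise_reduction_scales_as_sqrt_n():
    rng = np.random.default_rng(3)
    truth = np.full(450, 1000.0)
    reps = [
        UniformSeries(t0=0.0, dt=1.0, values=truth + rng.normal(0, 120.0, 450))
        for _ in range(8)
    ]
    resid_sd = (ensemble_average(reps).values - truth).std()
    assert resid_sd == pytest.approx(120.0 / np.sqrt(8), rel=0.15)


@settings(derandomize=True, max_examples=25)
@given(
    alpha=st.floats(-3, 3, allow_nan=False),
    beta=st.floats(-3, 3, allow_nan=False),
    op_index=st.integers(0, 2),
)
def test_preprocessing_operators_are_linear(alpha, beta, op_index):
    rng = np.random.default_rng(11)
    x = rng.normal(size=120)
    y = rng.normal(size=120)
    ops = [
        lambda s: moving_average(s, 5),
        lambda s: lowpass(s),
        lambda s: ensemble_average([s, s]),
    ]
    op = ops[op_index]
    mk = lambda v: UniformSeries(t0=0.0, dt=1.0, values=v)
    combined = op(mk(alpha * x + beta * y)).values
    separate = alpha * op(mk(x)).values + beta * op(mk(y)).values
    np.testing.assert_allclose(combined, separate, atol=1e-8)


@pytest.mark.parametrize("op", ["ma", "lp"])
def test_filters_preserve_period_mean(op, reference_response):
    filtered = (
        moving_average(reference_response, 7)
        if op == "ma"
        else lowpass(reference_response)
    )
    assert filtered.values.mean() == pytest.approx(
        reference_response.values.mean(), rel=1e-3
    )
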