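"""First-order simulator and breath-by-breath measurement model."""
import numpy as np
import pytest

from vo2mng import (
    EXTREME_TAUS,
    TABLE_SIMULATIONS,
    FirstOrderParams,
    analytic_mng,
    breath_sample,
    first_order_response,
    interpolate_1s,
    prbs_protocol,
    run_extreme_tau_study,
    run_table2_study,
)
from vo2mng.series import UniformSeries


def test_constant_high_input_converges_to_a0_plus_a1():
    proto = prbs_protocol(bits=[1] * 15)
    params = FirstOrderParams(300.0, 700.0, 15.0)
    out = first_order_response(proto, params, n_warmup_periods=4)
    assert out.values[-1] == pytest.approx(1000.0, abs=1e-6)


def test_steady_state_mapping_low_level():
    proto = prbs_protocol(bits=[0] * 15)
    out = first_order_response(proto, FirstOrderParams(300.0, 700.0, 15.0))
    np.testing.assert_allclose(out.values, 300.0, atol=1e-9)


def test_invalid_tau_rejected():
    with pytest.raises(ValueError, match="tau"):
        FirstOrderParams(300.0, 700.0, 0.0)


def test_response_matches_brute_force_convolution_oracle(protocol):
    """Final period equals the convolution of the input with the sampled
    impulse response of the exact zero-order-hold discretization."""
    params = FirstOrderParams(300.0, 700.0, 30.0)
    warm = 11
    n = protocol.period_samples
    u = np.tile(protocol.one_period(), warm + 1)
    gain = params.a1 / (protocol.high - protocol.low)
    drive = gain * (u - protocol.low)  # deviation input, ml/min
    alpha = np.exp(-protocol.dt / params.tau_s)
    # ZOH impulse response: zero at lag 0, (1-alpha)*alpha^(k-1) at lag k >= 1
    kernel = np.concatenate([[0.0], (1.0 - alpha) * alpha ** np.arange(u.size - 1)])
    conv = np.convolve(drive, kernel)[: u.size]
    oracle = params.a0 + conv
    sim = first_order_response(protocol, params, n_warmup_periods=warm)
    np.testing.assert_allclose(sim.values, oracle[-n:], rtol=1e-6)


def test_delay_shifts_response_in_time(protocol):
    base = first_order_response(protocol, FirstOrderParams(300.0, 700.0, 20.0, td=0.0))
    delayed = first_order_response(protocol, FirstOrderParams(300.0, 700.0, 20.0, td=7.0))
    # a pure delay of a periodic response is a circular shift
    np.testing.assert_allclose(delayed.values, np.roll(base.values, 7), rtol=1e-6)


def test_fractional_delay_matches_fine_grid_oracle():
    """A td that is not a multiple of dt must agree with a finer-grid
    simulation in which the same delay is an exact sample shift."""
    params = FirstOrderParams(300.0, 700.0, 20.0, td=3.5)
    coarse = first_order_response(prbs_protocol(dt=1.0), params, n_warmup_periods=8)
    fine = first_order_response(prbs_protocol(dt=0.5), params, n_warmup_periods=8)
    np.testing.assert_allclose(coarse.values, fine.values[::2], rtol=1e-6)


def test_warmup_extension_is_sufficient(protocol):
    """Adding warm-up periods beyond the default leaves the returned period
    unchanged to 1e-6 relative (for physiological tau)."""
    params = FirstOrderParams(300.0, 700.0, 100.0)
    default = first_order_response(protocol, params)
    longer = first_order_response(protocol, params, n_warmup_periods=20)
    np.testing.assert_allclose(default.values, longer.values, rtol=1e-6)


def test_table_study_matches_closed_form_oracle():
    table = run_table2_study()
    for _, row in table.iterrows():
        assert row.mng == pytest.approx(analytic_mng(row.tau_s), abs=1.0)


def test_mng_invariant_to_amplitude_parameters(protocol):
    """Normalization isolates tau: varying a0 and a1 over the study ranges
    moves MNG by less than 0.1 percentage point."""
    from vo2mng import gain_profile, harmonic_decomposition

    input_dec = harmonic_decomposition(protocol.to_uniform())
    mngs = []
    for a0 in (125.0, 400.0):
        for a1 in (600.0, 900.0):
            out = first_order_response(protocol, FirstOrderParams(a0, a1, 35.0))
            dec = harmonic_decomposition(out)
            mngs.append(gain_profile(input_dec, dec).mng)
    assert max(mngs) - min(mngs) < 0.1


def test_extreme_tau_study_limits_and_monotonicity():
    table = run_extreme_tau_study()
    sub = table[(table.h_lo == 2) & (table.h_hi == 4)].sort_values("tau_s")
    assert sub.mng.iloc[0] >= 99.9  # instantaneous system: flat gain
    # high-tau limit: 100 * mean(1/2, 1/3, 1/4)
    assert sub.mng.iloc[-1] == pytest.approx(100.0 * (1 / 2 + 1 / 3 + 1 / 4) / 3, abs=1.0)
    assert np.all(np.diff(sub.mng.to_numpy()) < 0)
    # wider harmonic ranges lower the high-tau plateau
    plateau = {
        (lo, hi): table[(table.h_lo == lo) & (table.h_hi == hi)].mng.min()
        for lo, hi in ((2, 3), (2, 4), (2, 10))
    }
    assert plateau[(2, 3)] > plateau[(2, 4)] > plateau[(2, 10)]


def test_breath_sample_deterministic_and_noiseless_roundtrip(reference_response):
    a = breath_sample(reference_response, noise_sd=0.0, interval_jitter=0.0, seed=7)
    b = breath_sample(reference_response, noise_sd=0.0, interval_jitter=0.0, seed=7)
    np.testing.assert_array_equal(a.times, b.times)
    np.testing.assert_array_equal(a.vo2, b.vo2)
    grid = interpolate_1s(a)
    truth = np.interp(grid.times, reference_response.times, reference_response.values)
    # noiseless round trip: only linear-interpolation error remains, bounded
    # by the slope jump at input switches (G*dW/tau) over a 3-s breath gap
    slope_jump = 700.0 / 35.0
    assert np.max(np.abs(grid.values - truth)) < slope_jump * 3.0 / 4.0 + 1.0


def test_breath_noise_sd_recovered_over_replicates():
    signal = UniformSeries(t0=0.0, dt=1.0, values=np.full(200, 1000.0))
    residuals = []
    for seed in range(300):
        b = breath_sample(signal, noise_sd=100.0, seed=seed)
        residuals.append(b.vo2 - 1000.0)
    sd = np.concatenate(residuals).std()
    assert sd == pytest.approx(100.0, rel=0.05)


def test_table_simulation_parameters_are_the_printed_ten():
    taus = [p.tau_s for p in TABLE_SIMULATIONS]
    assert taus == [15, 45, 25, 21, 39, 52, 42, 35, 48, 19]
    assert len(EXTREME_TAUS) == 10
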