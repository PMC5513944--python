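import numpy as np
import pytest

from vo2mng import (
    STEP_ALIGNED_SEED,
    FirstOrderParams,
    first_order_response,
    prbs_protocol,
)


@pytest.fixture(scope="session")
def protocol():
    """One 450-s PRBS period with the default register seed."""
    return prbs_protocol()


@pytest.fixture(scope="session")
def step_protocol():
    """PRBS period whose embedded step transition lands at 180 s."""
    return prbs_protocol(seed=STEP_ALIGNED_SEED)


@pytest.fixture(scope="session")
def reference_response(protocol):
    """Noiseless first-order response (a0=300, a1=700, tau=35 s)."""
    return first_order_response(protocol, FirstOrderParams(300.0, 700.0, 35.0))


def monoexp_series(a0, a, tau, td, t):
    """Delayed mono-exponential evaluated at times t (onset at 0)."""
    t = np.asarray(t, dtype=float)
    y = np.full_like(t, a0)
    on = t >= td
    y[on] = a0 + a * (1.0 - np.exp(-(t[on] - td) / tau))
    return y
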