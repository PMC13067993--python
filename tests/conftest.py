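import numpy as np
import pytest

from arselect.dgp import generate_series, get_condition


@pytest.fixture(scope="session")
def ar1_series_long():
    """Long stationary AR(1) series (phi=.7) for recovery checks."""
    return generate_series(get_condition("ar1_phi.7"), 10_000, 42).values


@pytest.fixture(scope="session")
def ar1_series_short():
    """T=100 AR(1) series (phi=.3)."""
    return generate_series(get_condition("ar1_phi.3"), 100, 7).values


@pytest.fixture(scope="session")
def white_noise_series():
    """T=50 i.i.d. N(0,1) series."""
    return generate_series(get_condition("white_noise"), 50, 3).values


@pytest.fixture
def noiseless_ar1():
    """Exact recursion y_t = .5 y_{t-1}, y_1 = 1 (no innovations)."""
    y = np.empty(30)
    y[0] = 1.0
    for t in range(1, 30):
        y[t] = 0.5 * y[t - 1]
    return y
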