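import numpy as np
import pytest

from dfret import Photophysics, make_distribution


@pytest.fixture(scope="session")
def chain_dist():
    """Broad ideal-chain shifted distribution used across solver tests."""
    return make_distribution("ideal_chain_shifted", b=18.0, r_min=3.0)


@pytest.fixture(scope="session")
def photo100():
    """tau_d = 100 ns, R0 = 10 A."""
    return Photophysics(tau_d=100.0, r0=10.0)


def dense_trapezoid(fn, lo, hi, n=1_000_001):
    """Independent dense-grid quadrature oracle."""
    x = np.linspace(lo, hi, n)
    return np.trapezoid(fn(x), x)
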