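import numpy as np
import pytest

from timecycle.types import Series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_series_2h48h():
    """Noiseless unit sine, period 24 h, sampled every 2 h for 48 h."""
    t = np.arange(0.0, 48.0, 2.0)
    return Series(t, np.sin(2 * np.pi * t / 24.0))


def make_series(values, dt=2.0):
    values = np.asarray(values, dtype=float)
    return Series(np.arange(len(values)) * dt, values)
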