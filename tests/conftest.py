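import numpy as np
import pytest

from actifuse.gaf import TriaxialSeries, WindowingConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_windowing():
    """Small windows so fixtures stay fast: 0.5 s at 100 Hz -> 16 px images."""
    return WindowingConfig(window_seconds=0.5, image_size=16, frames_per_sequence=5)


def make_series(n=1500, rate_hz=100.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate_hz
    x = 0.02 * rng.standard_normal(n)
    y = 0.02 * rng.standard_normal(n)
    z = 1.0 + 0.1 * np.sin(2 * np.pi * 0.7 * t) + 0.02 * rng.standard_normal(n)
    return TriaxialSeries(timestamps=t, x=x, y=y, z=z, rate_hz=rate_hz)


@pytest.fixture
def wrist_series():
    return make_series()


@pytest.fixture
def float64_engine():
    """Run the autodiff engine in float64 for finite-difference checks."""
    from actifuse.autodiff import get_default_dtype, set_default_dtype
    prev = get_default_dtype()
    set_default_dtype(np.float64)
    yield
    set_default_dtype(prev)
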