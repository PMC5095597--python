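import numpy as np
import pytest

from cestkit import (ExchangePool, SaturationScheme, SpinSystem, default_scheme,
                     water_pool)


@pytest.fixture
def water_system():
    return SpinSystem((water_pool(1.7, 0.14),))


@pytest.fixture
def amine_pool():
    return ExchangePool("amine", 2.8, 1600.0, 2e-3, 1.0, 0.01)


@pytest.fixture
def noe_pool():
    return ExchangePool("noe", -3.5, 20.0, 2e-3, 1.0, 0.005)


@pytest.fixture
def two_pool_system(amine_pool):
    return SpinSystem((water_pool(1.7, 0.14), amine_pool))


@pytest.fixture
def three_pool_system(amine_pool, noe_pool):
    """Baseline tumour-like phantom: water + amine (2.8 ppm) + NOE (-3.5)."""
    return SpinSystem((water_pool(1.7, 0.14), amine_pool, noe_pool))


@pytest.fixture
def short_scheme():
    """Abbreviated pulse train for unit tests (10 pulses, coarse grid)."""
    return SaturationScheme(
        mode="gaussian_train", n_pulses=10, pulse_duration=0.026,
        flip_angle=180.0, duty_cycle=0.5, n_segments=32,
        offsets=tuple(np.linspace(-8, 8, 33)))


@pytest.fixture
def full_scheme():
    return default_scheme()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
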