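import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spikewave.core import NO_SPIKE, SpikeTimeGrid, spike_times_to_wave

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_grid(rng, shape=(3, 4, 4), t_max=5, p_nospike=0.3) -> SpikeTimeGrid:
    """A random first-spike-time grid with a given no-spike probability."""
    times = rng.integers(0, t_max, size=shape)
    silent = rng.random(shape) < p_nospike
    times = np.where(silent, NO_SPIKE, times)
    return SpikeTimeGrid(times=times, t_max=t_max)


def random_wave(rng, shape=(3, 4, 4), t_max=5, p_nospike=0.3) -> np.ndarray:
    """A random valid accumulative spike-wave tensor."""
    return spike_times_to_wave(random_grid(rng, shape, t_max, p_nospike))
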