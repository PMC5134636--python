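import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cytopulse import GaussianPulseParams, TimeGrid, gaussian_pulse

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def grid():
    """Default acquisition grid: 10 MS/s, 2048 samples."""
    return TimeGrid(sample_period=1e-7, n_samples=2048)


@pytest.fixture
def gaussian_pair(grid):
    """Factory for a reference pulse and an analytically shifted copy."""

    def make(shift, amplitude=2.0, sigma=0.5e-6, center=None):
        c = center if center is not None else grid.start_time + 0.5 * grid.span
        ref = gaussian_pulse(GaussianPulseParams(amplitude, c, sigma), grid)
        sig = gaussian_pulse(GaussianPulseParams(amplitude, c + shift, sigma), grid)
        return ref, sig

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20231106)
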