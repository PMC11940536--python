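import numpy as np
import pytest

from ssvepsim.core import NoiseSpec, SimulationConfig
from ssvepsim.region import OscillatorWeights, RegionParams


@pytest.fixture
def alpha_noise():
    """Moderate external drive placing the region in the alpha regime."""
    return NoiseSpec(mu=220.0, sigma2=100.0)


@pytest.fixture
def short_cfg():
    """Short simulation config for fast unit tests."""
    return SimulationConfig(duration=2.0, burn_in=0.5, seed=0)


@pytest.fixture
def alpha_region(alpha_noise):
    """Alpha-dominant multi-dynamic region (weights 0.10/0.90/0.00)."""
    return RegionParams(weights=OscillatorWeights(0.10, 0.90, 0.00), noise=alpha_noise)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
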