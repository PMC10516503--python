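import numpy as np
import pytest

from pfsr.degrade import DegradationConfig, simulate_ulf_pair
from pfsr.phantom import Contrast, PhantomSpec, generate_labeled_phantom


@pytest.fixture(scope="session")
def t1_phantom64():
    """A default T1W-like 64³ phantom with its label field."""
    return generate_labeled_phantom(PhantomSpec(grid_size=64, seed=11))


@pytest.fixture(scope="session")
def ulf_pair64(t1_phantom64):
    """A simulated (32³ degraded input, 64³ clean target) pair."""
    cfg = DegradationConfig(pf_fraction=0.7, rician_sigma=0.05, seed=21)
    return simulate_ulf_pair(t1_phantom64.volume, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
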