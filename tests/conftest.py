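import numpy as np
import pytest

from guidedfusion import FusionConfig, generate_phantom_pair


@pytest.fixture(scope="session")
def phantom():
    """One fixed medium-size phantom pair shared across tests."""
    return generate_phantom_pair(size=128, seed=7, sigma=0.1)


@pytest.fixture
def default_cfg():
    return FusionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
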