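import numpy as np
import pytest

from hvnet.growth import HiddenVariableSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def powerlaw_spec():
    """Canonical sparse power-law hidden-variable distribution."""
    return HiddenVariableSpec(gamma=2.5, theta_min=1.0, theta_max=100.0)
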