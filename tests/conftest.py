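import numpy as np
import pytest

from telog4.simulate import SyntheticConfig


@pytest.fixture
def config():
    """Default study-condition generator configuration, fixed seed."""
    return SyntheticConfig(seed=42)


@pytest.fixture
def noiseless_config():
    return SyntheticConfig(seed=42, cd_noise_sd=0.0, emission_noise_sd=0.0,
                           cleavage_noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
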