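import numpy as np
import pytest

from herbnet import SynthConfig, load_packaged_herb


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def kushen():
    return load_packaged_herb("kushen")


@pytest.fixture(scope="session")
def baituling():
    return load_packaged_herb("baituling")


@pytest.fixture
def synth_config():
    return SynthConfig(seed=0)
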