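import numpy as np
import pytest

from boutonsort.specs import calibrate_default_mixtures


@pytest.fixture(scope="session")
def lm_spec():
    return calibrate_default_mixtures()[0]


@pytest.fixture(scope="session")
def dnm_spec():
    return calibrate_default_mixtures()[1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
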