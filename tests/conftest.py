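import numpy as np
import pytest

from notopattern.config import default_config, model_params_from_config


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def induction_params(cfg):
    return model_params_from_config("induction", cfg)


@pytest.fixture(scope="session")
def inhibition_params(cfg):
    return model_params_from_config("inhibition", cfg)


@pytest.fixture(scope="session")
def cistrans_params(cfg):
    return model_params_from_config("cistrans", cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
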