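import numpy as np
import pytest

from ideopeach import fruit_model as fm
from ideopeach import genetic_model as gm


@pytest.fixture(scope="session")
def model():
    return gm.default_genetic_model()


@pytest.fixture(scope="session")
def pairs():
    return gm.default_inseparable_pairs()


@pytest.fixture(scope="session")
def blocks(pairs):
    return gm.build_blocks(pairs)


@pytest.fixture(scope="session")
def growth_config():
    return fm.GrowthConfig()


@pytest.fixture(scope="session")
def weather():
    return fm.WeatherSeries.constant()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def intercept_params(model):
    return gm.predict_parameters(np.zeros(gm.N_LOCI, dtype=int), model)
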