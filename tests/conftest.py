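import numpy as np
import pytest

from nanosusp.config import (build_mixture, load_defaults,
                             load_pure_components)
from nanosusp.pcsaft import Mixture


@pytest.fixture(scope="session")
def components():
    return load_pure_components()


@pytest.fixture(scope="session")
def defaults():
    return load_defaults()


@pytest.fixture(scope="session")
def water_mixture(components):
    return Mixture([components["water"]])


@pytest.fixture(scope="session")
def fen_water(components):
    return build_mixture(("fenofibrate", "water"))


@pytest.fixture(scope="session")
def ternary(components):
    return build_mixture(("fenofibrate", "hpmc", "water"))


@pytest.fixture
def rng():
    return np.random.default_rng(20211022)
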