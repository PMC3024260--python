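import numpy as np
import pytest

from compdbn import load_complement
from compdbn.model_core import default_affinity_model
from compdbn.ode_sim import TimeGrid


@pytest.fixture(scope="session")
def complement():
    return load_complement()


@pytest.fixture(scope="session")
def affinity():
    return default_affinity_model()


@pytest.fixture(scope="session")
def short_grid():
    return TimeGrid.regular(2000.0, 100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
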