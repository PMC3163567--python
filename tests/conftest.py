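import numpy as np
import pytest

from readforge.error_model import QualityModel, make_synthetic_profile
from readforge.simulator import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rising_profile():
    """101-cycle profile rising 0.1% -> 5%, the standard test condition."""
    return make_synthetic_profile(101, 0.001, 0.05, "linear")


@pytest.fixture
def sim_cfg():
    return SimConfig()


@pytest.fixture
def informative_model():
    return QualityModel("error_informative")


@pytest.fixture
def average_model():
    return QualityModel("position_average")


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)].tolist())
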