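import numpy as np
import pytest

from refnav.environments import build_starmaze, build_vista_world
from refnav.neural_coding import NoiseModel


@pytest.fixture(scope="session")
def starmaze():
    return build_starmaze()


@pytest.fixture(scope="session")
def vista():
    return build_vista_world()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def no_noise():
    return NoiseModel(0.0, mode="off")
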