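import numpy as np
import pytest

from swingsim.dynamics import EndEffectorModel, PendulumParams


@pytest.fixture(scope="session")
def params() -> PendulumParams:
    return PendulumParams()


@pytest.fixture(scope="session")
def ee_model() -> EndEffectorModel:
    return EndEffectorModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
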