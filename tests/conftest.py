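import numpy as np
import pytest

from memfluo.fcs.model import AcfParams
from memfluo.fcs.zscan import InstrumentConfig


@pytest.fixture
def instrument() -> InstrumentConfig:
    return InstrumentConfig()


@pytest.fixture
def simple_params() -> AcfParams:
    return AcfParams(pn2d=5.0, tau2d=4.0e-3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
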