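import numpy as np
import pytest

from hemomap import AseProtocol, AslProtocol, PriorSpec, TissueConstants


@pytest.fixture(scope="session")
def const():
    return TissueConstants()


@pytest.fixture(scope="session")
def proto():
    return AseProtocol()


@pytest.fixture(scope="session")
def asl_proto():
    return AslProtocol()


@pytest.fixture(scope="session")
def priors():
    return PriorSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
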