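import numpy as np
import pytest

from leupet import FrameSchedule, make_input_functions, reference_library
from leupet.estimators import BasisSet


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default_protocol()


@pytest.fixture(scope="session")
def inputs():
    return make_input_functions()


@pytest.fixture(scope="session")
def basis(inputs, schedule):
    return BasisSet(inputs, schedule)


@pytest.fixture(scope="session")
def library():
    return reference_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
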