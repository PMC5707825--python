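import pytest

from clashscan.clash_engine import ClashParams
from clashscan.fixtures import make_cage, make_helix
from clashscan.predictor import DecisionParams, prepare_structure
from clashscan.rotamer_library import load_default_library


@pytest.fixture(scope="session")
def helix():
    s = make_helix(20, -57.0, -47.0)
    prepare_structure(s)
    return s


@pytest.fixture(scope="session")
def cage_tight():
    s = make_cage(2.0)
    prepare_structure(s)
    return s


@pytest.fixture(scope="session")
def cage_open():
    s = make_cage(15.0)
    prepare_structure(s)
    return s


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture()
def cparams():
    return ClashParams()


@pytest.fixture()
def dparams():
    return DecisionParams()
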