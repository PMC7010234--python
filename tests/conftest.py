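import pytest

from tcrforge.datasets import load_cmv_clonotypes
from tcrforge.germline import make_fixture_library
from tcrforge.simdata import build_default_scheme

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def germline_and_library():
    return make_fixture_library(FIXTURE_SEED)


@pytest.fixture(scope="session")
def germ(germline_and_library):
    return germline_and_library[0]


@pytest.fixture(scope="session")
def library(germline_and_library):
    return germline_and_library[1]


@pytest.fixture(scope="session")
def cmv_clonotypes():
    return load_cmv_clonotypes()


@pytest.fixture(scope="session")
def scheme():
    return build_default_scheme(rows=8, cols=12, bc_len=8, seed=7)
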