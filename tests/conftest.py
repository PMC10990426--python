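import pytest

from tagem.barcode_calling import CallingParams
from tagem.synthetic_data import DEFAULT_LAYOUT, generate_library


@pytest.fixture(scope="session")
def layout():
    return DEFAULT_LAYOUT


@pytest.fixture(scope="session")
def params():
    return CallingParams()


@pytest.fixture(scope="session")
def small_library():
    """A 500-barcode pool, large enough that collisions are rare."""
    return generate_library(500, 14, seed=7)


@pytest.fixture(scope="session")
def big_library():
    """A full-diversity pool matching the injected plasmid library."""
    return generate_library(20000, 14, seed=7)
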