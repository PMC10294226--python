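import numpy as np
import pytest

from rcdna.io_cli import FixtureSpec, make_fixture
from rcdna.rc_codec import encode

PAPER_BITS = 29_390


@pytest.fixture(scope="session")
def paper_data() -> bytes:
    return make_fixture(FixtureSpec(size_bits=PAPER_BITS, model="uniform", rng_seed=1))


@pytest.fixture(scope="session")
def paper_encoding(paper_data):
    """The in-library stand-in for the 29,390-bit / K=23 / m=2 scenario."""
    return encode(paper_data, bit_length=PAPER_BITS, m=2)


@pytest.fixture(scope="session")
def small_encoding():
    """K=4, m=2 encoding used by parsing/round-trip tests (cheap)."""
    data = make_fixture(FixtureSpec(size_bits=4 * 1278, model="uniform", rng_seed=9))
    return encode(data, m=2, search_budget=16, subset_samples=64)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
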