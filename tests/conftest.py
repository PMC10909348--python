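import numpy as np
import pytest

from bsperc import BSParams, bs_rvs, load_series


@pytest.fixture(scope="session")
def maehongson():
    return load_series("maehongson")


@pytest.fixture(scope="session")
def lampang():
    return load_series("lampang")


@pytest.fixture
def rng():
    return np.random.default_rng(20240229)


@pytest.fixture(scope="session")
def toy_sample():
    """Small BS(0.5, 2) sample for oracle-level checks."""
    return bs_rvs(BSParams(0.5, 2.0), 20, np.random.default_rng(7))
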