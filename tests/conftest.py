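import numpy as np
import pytest

from cuffgraph.geometry import CuffLayout


@pytest.fixture(scope="session")
def layout():
    """The reference cuff: 7 rings x 8 contacts = 56 channels."""
    return CuffLayout(7, 8)


@pytest.fixture(scope="session")
def small_layout():
    """A small cuff for brute-force oracles."""
    return CuffLayout(3, 4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
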