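import numpy as np
import pytest

from polyspread import netio


@pytest.fixture
def star6():
    return netio.make_graph("star", 6)


@pytest.fixture
def complete6():
    return netio.make_graph("complete", 6)


@pytest.fixture
def lattice3x3():
    return netio.make_graph("lattice2d_periodic", 3, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
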