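import numpy as np
import pytest

from capsim.lattice import build_lattice


@pytest.fixture(scope="session")
def square_07():
    return build_lattice("square", 0.7)


@pytest.fixture(scope="session")
def triangular_07():
    return build_lattice("triangular", 0.7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
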