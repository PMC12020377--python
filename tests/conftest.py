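import numpy as np
import pytest

from tetraloop.geometry import AtomMap
from tetraloop.synthetic import build_reference_scaffold


@pytest.fixture(scope="session")
def scaffold():
    return build_reference_scaffold()


@pytest.fixture(scope="session")
def atom_map():
    return AtomMap()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
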