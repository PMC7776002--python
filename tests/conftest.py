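import numpy as np
import pytest

from gnlsd.drl import ResponseModel
from gnlsd.peaks import constraint_mesh
from gnlsd.simulate import make_scheme


@pytest.fixture(scope="session")
def scheme60():
    """b=3000 s/mm2 shell: 1 b0 + 60 hemisphere directions."""
    return make_scheme(3000.0, 60)


@pytest.fixture(scope="session")
def response():
    """White-matter single-fiber tensor response [1.7, 0.2, 0.2]e-3 mm2/s."""
    return ResponseModel()


@pytest.fixture(scope="session")
def dict300():
    """The 300-direction FOD dictionary / CSD constraint mesh."""
    return constraint_mesh()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
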