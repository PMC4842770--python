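import numpy as np
import pytest

from cortimap import fixtures as fx


@pytest.fixture(scope="session")
def brain2():
    """162-vertex / 320-face brain-like ellipsoid."""
    return fx.make_brain_mesh(subdivisions=2)


@pytest.fixture(scope="session")
def brain3():
    """642-vertex / 1280-face brain-like ellipsoid."""
    return fx.make_brain_mesh(subdivisions=3)


@pytest.fixture(scope="session")
def montage(brain3):
    """The 4 x 16-contact case-study strip montage."""
    return fx.make_case_study_montage(brain3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
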