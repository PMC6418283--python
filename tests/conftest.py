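import numpy as np
import pytest
from hypothesis import settings

from ssvepmap import build_layout, build_reference, standard_montage

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def reference():
    """Default harmonic reference: 15 Hz, M=3, 500 Hz, 4 s."""
    return build_reference(15.0, 3, 500.0, 2000)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
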