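import numpy as np
import pytest

from tomowave import default_spline_bank, make_phantom, support_mask


@pytest.fixture(scope="session")
def bank():
    return default_spline_bank()


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom()


@pytest.fixture(scope="session")
def mask64(phantom64):
    return support_mask(phantom64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
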