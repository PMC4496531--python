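import numpy as np
import pytest

from neurofield import GridSpec, gaussian_kernel, gaussian_smoothing


@pytest.fixture
def grid64():
    return GridSpec(1, 10.0, 64)


@pytest.fixture
def grid256():
    return GridSpec(1, 8.0, 256)


@pytest.fixture
def grid1024():
    return GridSpec(1, 20.0, 1024)


@pytest.fixture
def gauss_kernel():
    return gaussian_kernel(1.0, 1.0)


@pytest.fixture
def phi_gauss(grid64):
    return gaussian_smoothing(grid64, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
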