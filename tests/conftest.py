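import numpy as np
import pytest

from bsidt import IlluminationSet, OpticalConfig, compute_tfs


@pytest.fixture(scope="session")
def small_config():
    """A 32x32x5 grid sized for the brute-force Born oracle."""
    return OpticalConfig(pixel_size=0.1, nx=32, ny=32, slice_thickness=0.3,
                         slice_offsets=tuple(range(-2, 3)))


@pytest.fixture(scope="session")
def small_ring(small_config):
    return IlluminationSet.ring(small_config, n_sources=16, snap_to_grid=True)


@pytest.fixture(scope="session")
def small_tfs(small_config, small_ring):
    return compute_tfs(small_config, small_ring)


@pytest.fixture(scope="session")
def bead_config():
    """The 64x64x9 closed-loop reconstruction grid."""
    return OpticalConfig(nx=64, ny=64, slice_offsets=tuple(range(-4, 5)))


@pytest.fixture(scope="session")
def bead_ring(bead_config):
    return IlluminationSet.ring(bead_config, n_sources=16)


@pytest.fixture(scope="session")
def bead_tfs(bead_config, bead_ring):
    return compute_tfs(bead_config, bead_ring)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
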