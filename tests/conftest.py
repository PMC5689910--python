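import numpy as np
import pytest

from fuse4d import PhantomSpec, make_phantom
from fuse4d.volume import Grid3D


@pytest.fixture(scope="session")
def small_phantom():
    """Small 3-bin phantom shared by tests that only read from it."""
    return make_phantom(PhantomSpec(bins=3, seed=11))


@pytest.fixture(scope="session")
def default_phantom():
    """Full 10-bin phantom at the default study layout."""
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture
def unit_grid():
    return Grid3D(np.zeros(3), np.ones(3), (10, 10, 10))


def random_orthonormal(rng):
    """Random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))
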