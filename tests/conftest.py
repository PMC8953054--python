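import numpy as np
import pytest

from placentex.phantom import PhantomConfig, generate_roi_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A 16x16 random 8-bit image."""
    return rng.integers(0, 256, size=(16, 16)).astype(np.uint8)


@pytest.fixture
def checkerboard():
    """0/1 checkerboard, 8x8."""
    r, c = np.indices((8, 8))
    return ((r + c) % 2).astype(np.uint8)


@pytest.fixture(scope="session")
def small_phantom_set():
    """A reduced phantom set (12 + 12 ROIs) shared across tests."""
    cfg = PhantomConfig(n_healthy=12, n_calcified=12, seed=7)
    return generate_roi_set(cfg)
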