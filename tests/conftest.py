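import numpy as np
import pytest

from mrordenoise import NoiseSpec, PhantomSpec, corrupt, make_phantom


@pytest.fixture(scope="session")
def phantom_128():
    """Default textured phantom at 128x128 (session-cached; treat as read-only)."""
    return make_phantom(PhantomSpec(height=128, width=128, seed=3))


@pytest.fixture(scope="session")
def flat_image():
    """Constant mid-gray 32x32 image."""
    return np.full((32, 32), 100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisy_pair(phantom_128):
    """(noisy, ground-truth mask) at 20% fixed-valued noise."""
    return corrupt(phantom_128, NoiseSpec(kind="fixed_valued", p=0.2, seed=1))
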