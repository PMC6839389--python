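import numpy as np
import pytest

from sonocad import Lesion, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_null_phantom():
    """Lesion-free 256x128 phantom (fast; 8x4 grid of 32-px blocks)."""
    return generate_phantom(PhantomSpec(height=256, width=128, seed=7))


@pytest.fixture(scope="session")
def small_lesion_phantom():
    """256x128 phantom with a block-aligned 64x64 hypoechoic lesion."""
    les = Lesion(position=(96, 32), size=(64, 64), drop=0.3, heterogeneity=0.3)
    return generate_phantom(
        PhantomSpec(height=256, width=128, lesions=(les,), label="malignant", seed=7)
    )
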