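import numpy as np
import pytest

from mtef.phantom import PhantomSpec, generate_pair
from mtef.volio import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """Textured 16³ volume in [0, 1]."""
    return Volume(rng.random((16, 16, 16)))


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic desk-scale phantom pair with labels and truth."""
    return generate_pair(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def mild_phantom_pair():
    """Low-amplitude phantom (small smooth deformation only)."""
    return generate_pair(
        PhantomSpec(seed=11, amplitude=2.0, organ_amplitude=1.0)
    )
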