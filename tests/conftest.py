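import logging

import numpy as np
import pytest

from trisr.networks import GeneratorSpec
from trisr.phantom import PhantomSpec, generate_phantom

# slices smaller than one HR patch are routinely skipped in tiny fixtures
logging.getLogger("trisr.slicing").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_phantom():
    """A small textured phantom with even dims (halves to even/even/odd)."""
    return generate_phantom(PhantomSpec(shape=(24, 24, 14), n_blobs=5, seed=11))


@pytest.fixture(scope="session")
def smooth_phantom():
    """Noise-free phantom for round-trip style checks."""
    return generate_phantom(
        PhantomSpec(shape=(20, 20, 12), n_blobs=4, noise_sigma=0.0, seed=7))


@pytest.fixture
def toy_g1_spec():
    return GeneratorSpec(kind="rfb_esrgan", n_rrdb=1, n_rrfdb=1,
                         base_channels=8, growth=4, scale=2)


@pytest.fixture
def toy_g2_spec():
    return GeneratorSpec(kind="nesrgan", n_rrdb=1, base_channels=8, growth=4,
                         scale=1, noise=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
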