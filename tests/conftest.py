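import numpy as np
import pytest

from speckleseg.denoise import PeronaMalikDenoiser
from speckleseg.phantom import generate_phantom


@pytest.fixture(scope="session")
def speckled_phantom():
    """Default-condition speckled bean phantom."""
    return generate_phantom(sigma=0.8, seed=1)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom (sigma = 0 limit)."""
    return generate_phantom(sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def denoised_speckled(speckled_phantom):
    den = PeronaMalikDenoiser()
    return den.fit(speckled_phantom.noisy).transform(speckled_phantom.noisy)


@pytest.fixture(scope="session")
def disc_phantom():
    """Noise-free disc for geometry-oracle tests."""
    return generate_phantom(shape=(96, 96), semi_axes=(20, 20), indent_depth=0.0,
                            sigma=0.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
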