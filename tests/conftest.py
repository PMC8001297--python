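import numpy as np
import pytest

from fnlm import NoiseSpec, PhantomSpec, add_gaussian_noise, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    """Seeded 32x32 single-channel image of uniform intensities."""
    return rng.uniform(0.0, 1.0, size=(32, 32))


@pytest.fixture(scope="session")
def small_phantom():
    """Clean 96x96 phantom with a handful of nuclei, plus its label grid."""
    spec = PhantomSpec(
        height=96, width=96, n_brown=4, n_blue=4, radius_range=(5.0, 9.0), seed=7
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom(small_phantom):
    img, labels = small_phantom
    noisy = add_gaussian_noise(img, NoiseSpec(gaussian_sigma=0.05, seed=3))
    return noisy, img, labels
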