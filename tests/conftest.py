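import numpy as np
import pytest

from tumoxmap import phantom
from tumoxmap.phantom import NoiseSpec, PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def truth():
    """Default noiseless 32^3 phantom with all regions."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def ase(truth):
    return phantom.simulate_flair_ase(truth)


@pytest.fixture(scope="session")
def small_truth():
    """Smaller phantom for the expensive DSC tests."""
    return build_phantom(PhantomSpec(grid_shape=(20, 20, 20)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_noisy_truth(sigma, seed=0, model="gaussian"):
    return build_phantom(PhantomSpec(noise=NoiseSpec(model=model, sigma=sigma), seed=seed))
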