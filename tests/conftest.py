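import numpy as np
import pytest

from synthce.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def clean_study_2d():
    """Noise-free, perfectly aligned 2D study with default geometry."""
    return generate_phantom(
        PhantomConfig(grid_shape=(64, 64), noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def clean_study_3d():
    return generate_phantom(
        PhantomConfig(grid_shape=(64, 64, 32), noise_sd=0.0, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
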