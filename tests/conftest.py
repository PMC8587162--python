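import numpy as np
import pytest

from vinemetrics import synthetic


@pytest.fixture(scope="session")
def berry_half_dead():
    """One synthetic berry with 55% living tissue, no seed."""
    return synthetic.make_berry_image(0.55, rng_seed=11)


@pytest.fixture(scope="session")
def canopy_scene():
    """One synthetic canopy scene, ff = 0.80, phi = 0.20."""
    return synthetic.make_canopy_scene(0.80, 0.20, rng_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
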