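import numpy as np
import pytest

import spioquant as sq


@pytest.fixture(scope="session")
def reference_phantom():
    """Noiseless packaged tube fixture (anchored concentration-T2 pairs)."""
    return sq.reference_phantom_spec(noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def small_scene_noiseless():
    """Small noiseless scene for fast pipeline tests."""
    spec = sq.reference_scene_spec(noise_sigma=0.0, seed=0, shape=(32, 32, 32))
    pre, post, truth = sq.simulate_scene(spec)
    return spec, pre, post, truth


@pytest.fixture(scope="session")
def small_scene_noisy():
    """Small noisy scene (S0/sigma = 50), fixed seed."""
    spec = sq.reference_scene_spec(noise_sigma=20.0, seed=7, shape=(32, 32, 32))
    pre, post, truth = sq.simulate_scene(spec)
    return spec, pre, post, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
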