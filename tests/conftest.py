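import numpy as np
import pytest

from flairacc.phantom import (generate_coil_sensitivities, generate_phantom)


@pytest.fixture(scope="session")
def case64():
    """Small phantom used across reconstruction tests."""
    return generate_phantom(shape=(64, 64), fov_mm=240.0, n_lesions=2, seed=5)


@pytest.fixture(scope="session")
def coils64(case64):
    return generate_coil_sensitivities(case64.shape, n_channels=6, seed=2)


@pytest.fixture(scope="session")
def case126():
    """Grid divisible by 3, for SENSE unfolding at AF=3."""
    return generate_phantom(shape=(126, 126), fov_mm=240.0, n_lesions=3, seed=11)


@pytest.fixture(scope="session")
def coils126(case126):
    return generate_coil_sensitivities(case126.shape, n_channels=8, seed=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
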