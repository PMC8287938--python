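import numpy as np
import pytest
from hypothesis import settings

from oligosaxs.synth import default_s_grid, sphere_curve

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")

RG_SPHERE_30 = 30.0 * (3.0 / 5.0) ** 0.5  # √(3/5)·R


@pytest.fixture(scope="session")
def s_grid():
    return default_s_grid()


@pytest.fixture(scope="session")
def sphere30():
    """Noiseless uniform sphere, R = 30 Å."""
    return sphere_curve(30.0)


@pytest.fixture(scope="session")
def sphere30_noisy():
    """Uniform sphere, R = 30 Å, 1% counting-like noise, fixed seed."""
    return sphere_curve(30.0, noise=0.01, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
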