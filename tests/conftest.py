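import numpy as np
import pytest

from hoogfit.core import FieldContext, RDProfile, SpinlockCondition, r1rho_profile
from hoogfit.synthetic import default_grid


@pytest.fixture(scope="session")
def field_c13():
    return FieldContext(700.0, "C13")


@pytest.fixture(scope="session")
def grid_full():
    """The default 44-condition carbon grid."""
    return default_grid("C13")


@pytest.fixture(scope="session")
def grid_small():
    """Reduced 20-condition grid for tests that refit many replicates."""
    return default_grid(
        "C13",
        onres_powers=(150.0, 400.0, 1000.0, 3500.0),
        offres_powers=(150.0, 1000.0),
        n_offsets=8,
    )


def make_profile(model, grid, noise_sd=0.0, seed=0, label="spin", temperature=None):
    """Noise-free or R1rho-level-noisy dispersion profile from a model."""
    r = r1rho_profile(model, grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.standard_normal(r.shape) * noise_sd
        err = tuple(np.full(len(grid), noise_sd))
    else:
        err = None
    return RDProfile(label, tuple(grid), tuple(r), err, temperature)


@pytest.fixture(scope="session")
def profile_factory():
    return make_profile
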