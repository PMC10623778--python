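import numpy as np
import pytest

from hepaseg.phantom import PhantomSpec, generate_phantom

SMALL_SPEC = PhantomSpec(
    grid_shape=(12, 64, 64),
    n_tumors=2,
    tumor_radius_range_mm=(4.0, 8.0),
    n_vessels=2,
    noise_sigma=0.05,
    seed=11,
)


@pytest.fixture(scope="session")
def small_case():
    """One small phantom shared by read-only tests."""
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free, vessel-free phantom with known plateau intensities."""
    return generate_phantom(
        PhantomSpec(
            grid_shape=(12, 64, 64),
            n_tumors=2,
            tumor_radius_range_mm=(4.0, 8.0),
            n_vessels=0,
            noise_sigma=0.0,
            seed=5,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
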