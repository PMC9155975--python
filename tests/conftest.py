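import numpy as np
import pytest

from gastroseg.phantoms import PhantomParams, generate_phantom


@pytest.fixture
def small_params() -> PhantomParams:
    """Easy-regime phantom: mild irregularity, mild heterogeneity, 96 px."""
    return PhantomParams(
        size=96,
        outer_radius=30.0,
        wall_thickness=8.0,
        boundary_irregularity=0.03,
        heterogeneity_sd=2.0,
        seed=7,
    )


@pytest.fixture
def small_phantom(small_params):
    return generate_phantom(small_params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
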