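import numpy as np
import pytest

from rnc.synthetic_cortex import (
    SyntheticCortexConfig,
    chain_areas,
    grouped_areas,
    simulate_hierarchy,
    toy_generator,
    toy_image_encoders,
)


@pytest.fixture(scope="session")
def toy_encoders():
    return toy_image_encoders()


@pytest.fixture(scope="session")
def generator():
    return toy_generator()


@pytest.fixture(scope="session")
def small_chain():
    """4-area chain, 3 participants, modest size: fast shared fixture."""
    cfg = SyntheticCortexConfig(
        n_participants=3,
        areas=chain_areas(),
        n_images=600,
        voxels_per_area=40,
        noise_sd=0.3,
        seed=7,
    )
    return cfg, *simulate_hierarchy(cfg)


@pytest.fixture(scope="session")
def grouped_cortex():
    cfg = SyntheticCortexConfig(
        n_participants=2,
        areas=grouped_areas(),
        n_images=600,
        voxels_per_area=40,
        noise_sd=0.3,
        seed=11,
    )
    return cfg, *simulate_hierarchy(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
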