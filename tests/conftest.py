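import numpy as np
import pytest

from myoseg import PhantomConfig, generate_domain_datasets, generate_phantom_slice, sample_subject_geometry


@pytest.fixture(scope="session")
def geometry():
    cfg = PhantomConfig(seed=0)
    return sample_subject_geometry(cfg, np.random.default_rng(5))


@pytest.fixture(scope="session")
def easy_slice_noiseless(geometry):
    cfg = PhantomConfig(noise_sd=0.0, infiltration_fraction=0.0, seed=0)
    return generate_phantom_slice(cfg, geometry, 11)


@pytest.fixture(scope="session")
def hard_slice_noiseless(geometry):
    cfg = PhantomConfig(noise_sd=0.0, infiltration_fraction=0.5, seed=0)
    return generate_phantom_slice(cfg, geometry, 11)


@pytest.fixture(scope="session")
def small_datasets():
    """4 easy + 4 hard subjects, 3 slices each, default study conditions."""
    return generate_domain_datasets(4, 4, 3, PhantomConfig(seed=7))
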