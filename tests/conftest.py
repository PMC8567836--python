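import numpy as np
import pytest

from r2sn import (CohortSpec, PhantomSpec, extract_region_features,
                  full_catalog, make_cohort, make_phantom)


@pytest.fixture(scope="session")
def small_phantom():
    """12-region textured phantom small enough for fast extraction."""
    spec = PhantomSpec(shape=(18, 12, 12), n_regions=12, n_classes=3, seed=11)
    vol, truth = make_phantom(spec)
    return vol, truth


@pytest.fixture(scope="session")
def small_phantom_features(small_phantom):
    vol, _ = small_phantom
    return extract_region_features(vol, full_catalog())


@pytest.fixture(scope="session")
def small_cohort():
    """20-subject single-session similarity-matrix cohort."""
    spec = CohortSpec(n_subjects=20, n_sessions=1, n_regions=30, n_modules=5,
                      seed=5)
    stack, truth = make_cohort(spec)
    return stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
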