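import numpy as np
import pytest

from b0dti import CohortConfig, default_scheme, default_tissue


@pytest.fixture(scope="session")
def tissue():
    """Reference stick+zeppelin voxel: [2.6, 2, 0.4] um^2/ms, R2_i = 12 1/s,
    R2_e = 17.4 + 2.4 sin^4(theta) 1/s, f = 0.4."""
    return default_tissue()


@pytest.fixture(scope="session")
def scheme_te54():
    return default_scheme(te_list=(54.0,)).subset_te(54.0)


@pytest.fixture(scope="session")
def multi_te_scheme():
    return default_scheme(te_list=(54.0, 75.0))


@pytest.fixture(scope="session")
def small_cohort_config():
    return CohortConfig(
        n_subjects=1,
        n_tracts=4,
        n_segments_per_tract=6,
        n_voxels_per_segment=5,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
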