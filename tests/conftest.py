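import numpy as np
import pytest

from decparc import SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def blob_data():
    """Two well-separated 10-feature Gaussian blobs (D=10, n=60), centers 6 apart."""
    r = np.random.default_rng(42)
    center = np.zeros(10)
    center[:5] = 3.0
    c1 = r.normal(0, 0.05, (30, 10)) + center
    c2 = r.normal(0, 0.05, (30, 10)) - center
    X = np.vstack([c1, c2]).T
    truth = np.r_[np.zeros(30, int), np.ones(30, int)]
    return X, truth


@pytest.fixture
def small_spec():
    """Down-scaled synthetic cohort for fast pipeline tests."""
    return SyntheticSpec(
        n_subjects=2, n_scans_per_subject=6, grid_shape=(3, 12, 2),
        n_rois=30, T=240, seed=7,
    )
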