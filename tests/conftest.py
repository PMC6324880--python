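import numpy as np
import pytest
from hypothesis import settings

from wmconn.atlas import make_atlas

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from wmconn.model import SparseBayesianRegression
from wmconn.simulate import make_ground_truth, simulate_cohort


@pytest.fixture(scope="session")
def atlas18():
    return make_atlas()


@pytest.fixture(scope="session")
def atlas_small():
    return make_atlas(4, 10)


@pytest.fixture(scope="session")
def ground_truth(atlas18):
    return make_ground_truth(atlas18, seed=11)


@pytest.fixture(scope="session")
def training_cohort(atlas18, ground_truth):
    """Default-SNR healthy training cohort (n=100) with its design matrices."""
    recs = simulate_cohort(100, ("HC",), ground_truth, atlas18, seed=21)
    X = np.vstack([r.fc for r in recs])
    y = np.array([r.wma_true for r in recs])
    return recs, X, y


@pytest.fixture(scope="session")
def fitted_model(training_cohort):
    _, X, y = training_cohort
    return SparseBayesianRegression().fit(X, y)
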