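import numpy as np
import pytest

from contextnets.fixtures import PlantedCohortSpec, generate_planted_cohort
from contextnets.simulate import ContextVaryingGaussianSpec, sample_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gaussian5(rng):
    """1,000 i.i.d. draws of a 5-gene Gaussian with a nontrivial covariance."""
    A = rng.normal(size=(5, 5))
    cov = A @ A.T / 5 + np.eye(5)
    X = rng.multivariate_normal(np.zeros(5), cov, size=1000)
    return X


@pytest.fixture(scope="session")
def sim2000():
    """Context-varying Gaussian: 2,000 contexts x 1 sample."""
    return sample_dataset(
        ContextVaryingGaussianSpec(n_contexts=2000, samples_per_context=1, seed=7)
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """3-subtype planted cohort with 2 informative and 2 noise context features."""
    return generate_planted_cohort(
        PlantedCohortSpec(n_per_subtype=150, context_informativeness=0.5, seed=5)
    )


def standardized(X):
    """z-score columns; helper shared by oracle tests."""
    X = np.asarray(X, dtype=float)
    return (X - X.mean(axis=0)) / X.std(axis=0)
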