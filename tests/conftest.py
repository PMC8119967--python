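import numpy as np
import pandas as pd
import pytest

from ptsdgps.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with clear group signal, cheap enough for model tests."""
    config = CohortConfig(n_group1=24, n_group2=8, seed=11)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A very small cohort for LOSO-level tests."""
    config = CohortConfig(n_group1=9, n_group2=4, seed=5)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def separable_features():
    """A subject-level feature matrix with a wide class margin."""
    rng = np.random.default_rng(3)
    n1, n2 = 30, 12
    X1 = rng.normal(0.0, 1.0, size=(n1, 4))
    X2 = rng.normal(6.0, 1.0, size=(n2, 4))
    subjects = [f"S{i:03d}" for i in range(n1 + n2)]
    X = pd.DataFrame(np.vstack([X1, X2]), index=subjects)
    X.columns = [f"f{j}" for j in range(4)]
    labels = pd.Series([1] * n1 + [2] * n2, index=subjects)
    return X, labels
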