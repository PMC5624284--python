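import numpy as np
import pandas as pd
import pytest

from gutmeta import AbundanceTable, CohortConfig, simulate_cohort
from gutmeta.lefse import metacommunity_scheme


def make_counts(X, sample_prefix="S", feature_prefix="T"):
    X = np.asarray(X)
    return AbundanceTable(
        pd.DataFrame(
            X.astype(np.int64),
            index=[f"{sample_prefix}{i}" for i in range(X.shape[0])],
            columns=[f"{feature_prefix}{j}" for j in range(X.shape[1])],
        ),
        mode="counts",
    )


def make_relative(X, sample_prefix="S", feature_prefix="T"):
    X = np.asarray(X, dtype=float)
    X = X / X.sum(axis=1, keepdims=True)
    return AbundanceTable(
        pd.DataFrame(
            X,
            index=[f"{sample_prefix}{i}" for i in range(X.shape[0])],
            columns=[f"{feature_prefix}{j}" for j in range(X.shape[1])],
        ),
        mode="relative",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The documented default cohort: 54 CT + 49 CD across 3 metacommunities."""
    return simulate_cohort(CohortConfig.default(42))


@pytest.fixture(scope="session")
def default_rel(default_cohort):
    return default_cohort.counts.to_relative()


@pytest.fixture(scope="session")
def truth_scheme(default_cohort):
    """Comparison scheme built from the generator's true component labels."""
    return metacommunity_scheme(
        default_cohort.truth["labels"], default_cohort.metadata.disease_status
    )
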