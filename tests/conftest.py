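import numpy as np
import pandas as pd
import pytest

from gutmwas import CohortConfig, CovariateSpec, generate_cohort

TECHNICAL_TERMS = ["case_status", "total_sequence_count", "collection_kit"]


@pytest.fixture(scope="session")
def planted_cohort():
    """Standard cohort with planted effects and clusters, shared across tests."""
    cfg = CohortConfig(
        n_cases=200,
        n_controls=200,
        n_clusters=3,
        cluster_size_range=(8, 8),
        covariate_specs=[CovariateSpec("laxatives", 3.8, 0.11)],
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_null_cohort():
    """Small cohort with nothing planted (fast stages, degenerate-case probing)."""
    cfg = CohortConfig(
        n_cases=30, n_controls=30, n_features=40, n_differential=0, depth_log_mean=np.log(1e5), seed=7
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_counts(array, prefix="f"):
    arr = np.asarray(array)
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )
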