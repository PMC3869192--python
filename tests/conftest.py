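import numpy as np
import pandas as pd
import pytest

from gutage import (FunctionalProfileMatrix, SampleRecord, SyntheticConfig,
                    default_planted_effects, generate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_matrix():
    """Hand-sized 4-sample x 5-feature count table."""
    frame = pd.DataFrame(
        [
            [4.0, 4.0, 0.0, 1.0, 2.0],
            [0.0, 4.0, 3.0, 1.0, 2.0],
            [0.0, 0.0, 5.0, 1.0, 2.0],
            [2.0, 0.0, 0.0, 1.0, 2.0],
        ],
        index=["S1", "S2", "S3", "S4"],
        columns=["A", "B", "C", "D", "E"],
    )
    return FunctionalProfileMatrix(frame, namespace="pfam")


@pytest.fixture
def small_records():
    return [
        SampleRecord("S1", 30, "Spain"),
        SampleRecord("S2", 40, "Spain"),
        SampleRecord("S3", 55, "Denmark"),
        SampleRecord("S4", 62, "Denmark"),
    ]


@pytest.fixture(scope="session")
def planted_cohort():
    """Default-condition synthetic cohort with the standard planted panel."""
    config = SyntheticConfig(planted=default_planted_effects(40), seed=11)
    return generate_cohort(config)


def random_count_matrix(rng, n_samples, n_features, density=0.5, scale=20.0):
    """Sparse random non-negative count matrix for oracle comparisons."""
    present = rng.random((n_samples, n_features)) < density
    counts = rng.poisson(scale, size=(n_samples, n_features)).astype(float) + 1.0
    counts[~present] = 0.0
    width = len(str(n_features))
    frame = pd.DataFrame(
        counts,
        index=[f"S{i}" for i in range(n_samples)],
        columns=[f"f{j:0{width}d}" for j in range(n_features)],
    )
    return FunctionalProfileMatrix(frame, namespace="pfam")
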