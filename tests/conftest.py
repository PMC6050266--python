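import numpy as np
import pandas as pd
import pytest

from ksvar import ExpressionMatrix, SampleMetadata, simulate_matrix


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples TPM matrix with annotations."""
    values = pd.DataFrame(
        {
            "s1": [100.0, 5.0, 0.0],
            "s2": [200.0, 12.0, 0.5],
            "s3": [150.0, 9.0, 0.0],
            "s4": [120.0, 11.0, 1.0],
        },
        index=["gA", "gB", "gC"],
    )
    ann = pd.DataFrame(
        {
            "symbol": ["A", "B", "C"],
            "biotype": ["protein_coding", "miRNA", "protein_coding"],
            "length_bp": [1000, 2000, 1500],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return ExpressionMatrix(values, units="TPM", annotations=ann)


@pytest.fixture
def tiny_meta():
    tab = pd.DataFrame(
        {"group": ["case", "case", "control", "control"], "age": [60.0, 58, 61, 63]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SampleMetadata(tab)


@pytest.fixture(scope="session")
def small_cohort():
    """400-gene synthetic cohort with planted effects, shared across tests."""
    return simulate_matrix(400, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
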