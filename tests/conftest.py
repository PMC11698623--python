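import numpy as np
import pandas as pd
import pytest

from modulemir import SimConfig, simulate_dataset
import modulemir.preprocessing as pp


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def normalized_genes(default_dataset):
    ds = default_dataset
    samples = pp.select_samples(
        ds.clinical, ds.gene_counts.columns, ds.mirna_counts.columns
    )
    counts = pp.filter_low_counts(ds.gene_counts[samples], 50)
    return pp.normalize_log2(counts)


@pytest.fixture
def small_expr():
    """Tiny deterministic expression matrix (6 genes x 8 samples)."""
    rng = np.random.default_rng(3)
    return pd.DataFrame(
        rng.normal(size=(6, 8)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(8)],
    )


def make_clinical(rows):
    """Helper: clinical table from (sample, stage, T, N, M, pharm, rad) rows."""
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "stage", "T", "N", "M",
            "pharmaceutical_treatment", "radiation_treatment",
        ],
    )
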