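import numpy as np
import pandas as pd
import pytest

from senescape import single_cell
from senescape import synthetic_data as syn


@pytest.fixture(scope="session")
def sc_adata():
    """Default synthetic scRNA-seq cohort (3 types, planted markers)."""
    adata = syn.gen_scrna(syn.ScCohortSpec(seed=5))
    single_cell.lognormalize(adata)
    return adata


@pytest.fixture(scope="session")
def bulk_tissue():
    """One synthetic tissue with a 50-gene correlated module."""
    spec = syn.BulkCohortSpec(
        n_tissues=1, n_genes=200, n_samples_per_tissue=50,
        modules_per_tissue=((40, 0.7),), seed=21)
    tissues, truth = syn.gen_bulk_cohort(spec)
    return tissues["tissue1"], truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Library-size-normalized log expression, for correlation checks."""
    libs = counts.sum(axis=0)
    return np.log1p(counts / libs * 1e6)
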