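import numpy as np
import pandas as pd
import pytest

from sexde.io import ExpressionMatrix, SampleTable
from sexde.simulate import SimConfig, generate_cohort

ALL_COVARIATES = ["RIN", "age", "PMI", "lobe", "pH"]


@pytest.fixture(scope="session")
def null_cohort():
    """Small null cohort: no planted effects, markers present."""
    cfg = SimConfig(n_subjects_per_sex=5, n_regions_per_subject=3, n_genes=600, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with one male-biased planted set (log2FD = log2(1.3))."""
    cfg = SimConfig(
        n_subjects_per_sex=10, n_regions_per_subject=3, n_genes=2000,
        planted_sets=[("planted", 100, float(np.log2(1.3)))], seed=23,
    )
    return generate_cohort(cfg)


def toy_matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def toy_samples(rows: dict) -> SampleTable:
    """Build a SampleTable from a dict of column -> list keyed by sample order."""
    df = pd.DataFrame(rows)
    return SampleTable(df.set_index("sample"))
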