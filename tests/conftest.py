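import numpy as np
import pandas as pd
import pytest

from spitzsig import (
    CountCohort,
    SyntheticConfig,
    generate_cohort,
    normalize_voom,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort: 120 genes, 12/6/8 samples, planted DE + signature."""
    cfg = SyntheticConfig(
        n_per_group=(12, 6, 8),
        n_genes=120,
        n_housekeeping=10,
        n_de_genes=10,
        de_logfc=1.5,
        n_signature_genes=4,
        signature_step=1.2,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_expr(small_cohort):
    return normalize_voom(small_cohort)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects: all genes exchangeable across groups."""
    cfg = SyntheticConfig(
        n_per_group=(12, 6, 8),
        n_genes=150,
        n_housekeeping=10,
        n_de_genes=0,
        n_signature_genes=0,
        seed=5,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_expr(null_cohort):
    return normalize_voom(null_cohort)


@pytest.fixture
def toy_cohort():
    """Tiny hand-built cohort for exact bookkeeping checks."""
    counts = pd.DataFrame(
        {"s1": [1, 2, 7], "s2": [4, 6, 10]},
        index=["g1", "g2", "g3"],
    )
    group = pd.Series(["SN", "MST"], index=["s1", "s2"])
    role = pd.Series(["housekeeping", "endogenous", "endogenous"], index=counts.index)
    return CountCohort(counts=counts, group=group, gene_role=role)
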