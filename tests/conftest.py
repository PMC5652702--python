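import numpy as np
import pandas as pd
import pytest

from osintegrate.diffexpr import CountMatrix
from osintegrate.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across read-only tests."""
    cfg = SimConfig(seed=7, n_genes=600, n_pathways=20, n_compounds=20,
                    n_kinases=15, baseline_mean=60.0)
    return simulate_cohort(cfg)


@pytest.fixture
def toy_counts():
    """4 samples (2 vs 2), 6 genes, hand-sized counts."""
    counts = pd.DataFrame(
        {
            "A1": [10, 100, 0, 50, 5, 0],
            "A2": [12, 110, 0, 55, 7, 0],
            "C1": [11, 95, 10, 48, 6, 0],
            "C2": [9, 105, 12, 52, 4, 0],
        },
        index=[f"g{i}" for i in range(6)],
    )
    groups = pd.Series(
        {"A1": "aggressive", "A2": "aggressive", "C1": "curable", "C2": "curable"}
    )
    return CountMatrix(counts=counts, groups=groups)


def make_dose_df(rows):
    return pd.DataFrame(
        rows,
        columns=["compound", "culture", "concentration_nM", "replicate", "viability"],
    )


@pytest.fixture
def dose_df_factory():
    return make_dose_df
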