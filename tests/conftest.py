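import numpy as np
import pandas as pd
import pytest

from micropair import (
    AbundanceTable,
    CohortMetadata,
    SyntheticConfig,
    generate_cohort,
)


def simplex_table(values, sample_ids=None, taxa=None) -> AbundanceTable:
    """Small helper: build a table from raw rows, renormalizing."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, k = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    taxa = taxa or [f"k__Bacteria|s__Taxon_{j}" for j in range(k)]
    return AbundanceTable.normalized(
        pd.DataFrame(values, index=sample_ids, columns=taxa)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One full-scale synthetic cohort (53 cases / 47 controls, 424 taxa)."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort without the rare-taxon block, for fast stages."""
    cfg = SyntheticConfig(
        seed=7, n_taxa=80, n_rare_removable=0, spike_min_rank=10, spike_max_rank=70
    )
    return generate_cohort(cfg), cfg


@pytest.fixture
def two_group_meta():
    def make(case_ids, control_ids):
        ids = list(case_ids) + list(control_ids)
        return CohortMetadata(
            pd.DataFrame(
                {"group": ["case"] * len(case_ids) + ["control"] * len(control_ids)},
                index=ids,
            )
        )

    return make
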