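import numpy as np
import pandas as pd
import pytest

import plaqniche as pq
from plaqniche.diffexp import DesignSpec

#: design used by the cohort-level DE tests: the standardized donor
#: covariates the pipeline adjusts for
COHORT_DESIGN = DesignSpec(
    covariates=(
        ("sex", "categorical"),
        ("age", "continuous"),
        ("gdna_pct", "continuous"),
    )
)


@pytest.fixture(scope="session")
def small_null_cohort():
    """Null cohort (no planted effects) at reduced scale for unit tests."""
    params = pq.SynthParams(
        seed=11, n_niche_genes=0, n_group_genes=0, n_genes=400, spots_per_donor=300
    )
    return pq.simulate_cohort(params, seed=11)


@pytest.fixture()
def grid11():
    """11 x 11 all-gray-matter grid at standard pitch/diameter."""
    return pq.make_spot_grid(11, 11, 100.0, 55.0)


def interior_spot(grid, row=5, col=5):
    return grid.spots.query("array_row == @row and array_col == @col")["spot_id"].iloc[0]
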