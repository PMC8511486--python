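import numpy as np
import pytest

from scnet import CohortSpec, generate_cohort, residualize


@pytest.fixture(scope="session")
def small_cohort():
    """Fast two-group cohort: 20 regions, 4 modules, 12+12 subjects."""
    spec = CohortSpec(
        n_regions=20,
        n_per_group=(12, 12),
        n_modules=4,
        within_r_by_group=(0.6, 0.4),
        between_r=0.1,
        seed=42,
    )
    table, truth = generate_cohort(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def small_residuals(small_cohort):
    _, table, _ = small_cohort
    resid = residualize(table)
    groups = {
        g: resid.rows_for(table.loc[table["group"] == g, "subject_id"])
        for g in ("control", "patient")
    }
    return resid, groups


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
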