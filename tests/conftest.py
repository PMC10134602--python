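import numpy as np
import pandas as pd
import pytest

import reboundomics as rb


@pytest.fixture(scope="session")
def balanced_config():
    """8 donors per group, four timepoints, small planted rebound."""
    return rb.CohortConfig(
        n_donors_per_group={"MS": 8, "HC": 8},
        timepoints=("T1", "T2", "T3", "PP"),
        n_cpgs=1000,
        n_genes=600,
        frac_rebound=0.02,
        effect_m=2.0,
        effect_lfc=2.0,
        rho_donor=0.5,
        dispersion=0.1,
        missing_pattern={},
        seed=20240101,
    )


@pytest.fixture(scope="session")
def cohort(balanced_config):
    """Generated cohort shared across tests (read-only)."""
    return rb.generate_cohort(balanced_config)


@pytest.fixture(scope="session")
def null_fits():
    """OLS-equivalent fits on pure-noise data with a simple design."""
    rng = np.random.default_rng(99)
    n, p, g = 24, 4, 400
    x = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    design = pd.DataFrame(x, columns=["intercept", "c1", "c2", "c3"],
                          index=[f"s{i}" for i in range(n)])
    donors = pd.Series([f"d{i // 2}" for i in range(n)], index=design.index)
    y = rng.normal(size=(g, n))
    data = rb.OmicsMatrix(
        pd.DataFrame(y, index=[f"f{i}" for i in range(g)], columns=design.index), "m"
    )
    dm = rb.DesignMatrix(design, donors, reference_time="T1")
    return data, dm
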