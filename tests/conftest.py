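import numpy as np
import pandas as pd
import pytest

from methyldx.simcohort import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """RA-vs-healthy cohort with planted RA effects, shared across tests."""
    cfg = SimConfig(
        group_sizes={"ra_seropos": 50, "healthy": 50},
        n_probes=500,
        n_ra_specific=10,
        n_inflammation=10,
        n_age_probes=10,
        n_sex_probes=10,
        delta_ra=1.5,
        seed=7,
    )
    beta, sheet, truth = simulate_cohort(cfg)
    return cfg, beta, sheet, truth


@pytest.fixture()
def tiny_beta():
    return pd.DataFrame(
        [[0.1, 0.2], [0.5, 0.6], [0.8, 0.9]],
        index=pd.Index(["cg00000001", "cg00000002", "cg00000003"], name="probe_id"),
        columns=["s1", "s2"],
    )
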