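import numpy as np
import pandas as pd
import pytest

import certscore as cs
from certscore import scoring


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A modest simulated cohort shared across read-only tests."""
    return cs.simulate_cohort(cs.default_finrisk_config(n_subjects=800, seed=42))


@pytest.fixture(scope="session")
def tiefree_lipids() -> pd.DataFrame:
    """1000 subjects with continuous, tie-free lipid values."""
    rng = np.random.default_rng(7)
    n = 1000
    df = pd.DataFrame({"subject_id": [f"T{i:04d}" for i in range(n)]})
    for name in scoring.LIPID_SPECIES:
        df[name] = np.exp(rng.normal(0.0, 0.4, size=n))
    return df


def single_effect_config(n: int, seed: int, beta_or: float = 0.10, beta_hr: float = 0.08):
    """Generator config whose only outcome driver is the CERT2 total."""
    c = cs.default_finrisk_config(n_subjects=n, seed=seed)
    c.prevalent_logit_coefs = {"intercept": -2.1, "cert2": beta_or}
    c.incident_log_hr_coefs = {"cert2": beta_hr}
    c.baseline_hazard_params = {"shape": 5.0, "scale": 90.0}
    return c
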