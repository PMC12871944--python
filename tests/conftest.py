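import logging

import numpy as np
import pandas as pd
import pytest

import phenorisk as pr

logging.getLogger("phenorisk").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort() -> pr.Cohort:
    """12 users x 8 days, full default missingness; shared across tests."""
    cfg = pr.CohortConfig(n_users=12, n_days=8, seed=7)
    return pr.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort) -> pr.FeatureMatrix:
    return pr.assemble_daily_features(small_cohort)


@pytest.fixture(scope="session")
def active_only_cohort() -> pr.Cohort:
    """Cohort with every sensor disabled (self-reports only); fast to build."""
    cfg = pr.CohortConfig(
        n_users=40, n_days=10, seed=3,
        sensor_optin_rates={k: 0.0 for k in pr.CohortConfig().sensor_optin_rates},
        zero_sensor_fraction=1.0,
    )
    return pr.generate_cohort(cfg)


def toy_scores(**overrides) -> pd.DataFrame:
    base = {"user_id": ["u0"], "sdq_total": [10], "sci_total": [20],
            "ed15_total": [1.0], "si_frequency": [0]}
    base.update({k: [v] for k, v in overrides.items()})
    return pd.DataFrame(base)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
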