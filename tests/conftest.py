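import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svmewma import (
    CohortConfig,
    ResidualPool,
    fit_aft,
    fit_svr,
    generate_cohort,
    sr_aft,
    sr_svm,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def phase1_cohort():
    """Uncensored Phase-I cohort at the published AFT coefficients."""
    return generate_cohort(
        CohortConfig(n=5000, censor_horizon_days=math.inf, seed=42)
    )


@pytest.fixture(scope="session")
def aft_fit_phase1(phase1_cohort):
    return fit_aft(phase1_cohort)


@pytest.fixture(scope="session")
def aft_pool(phase1_cohort, aft_fit_phase1):
    return ResidualPool.from_series(sr_aft(phase1_cohort, aft_fit_phase1))


@pytest.fixture(scope="session")
def svr_fit_phase1(phase1_cohort):
    x = np.array([r.parsonnet for r in phase1_cohort], dtype=float)
    y = np.log([r.time_days for r in phase1_cohort])
    return fit_svr(x, y)


@pytest.fixture(scope="session")
def svm_pool(phase1_cohort, svr_fit_phase1):
    return ResidualPool.from_series(sr_svm(phase1_cohort, svr_fit_phase1))
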