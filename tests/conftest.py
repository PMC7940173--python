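import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import amyscreen as amy

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default cohort shared by read-only tests."""
    return amy.generate_cohort(amy.default_cohort_spec(seed=7))


@pytest.fixture(scope="session")
def analysis_table(default_cohort):
    """Analysis-ready table with derived ratio/composite columns."""
    return amy.prepare_analysis_table(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
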