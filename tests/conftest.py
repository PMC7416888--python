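import numpy as np
import pytest

from cuecatch import default_config, default_likelihoods, default_priors, generate_cohort
from cuecatch.cohort import CohortParams, generate_control_cohort


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def likelihoods():
    return default_likelihoods()


@pytest.fixture(scope="session")
def exp1_schedule():
    """One full default exp1 schedule (shared; treat as read-only)."""
    from cuecatch import build_schedule

    return build_schedule(default_config("exp1"), np.random.default_rng(42))


@pytest.fixture(scope="session")
def internal_noise_cohort():
    """12-subject internal-noise-strategy exp1 cohort plus control task."""
    log, subjects = generate_cohort(
        "exp1", 12, CohortParams(strategy="internal_noise"), seed=7
    )
    control = generate_control_cohort(subjects, 100, seed=8)
    return log, subjects, control
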