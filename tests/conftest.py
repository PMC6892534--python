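import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.stats import norm

import collidersim as cs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: z-scale diagnosis threshold: (6.5 - 5.8) / 1.0
THRESHOLD_Z = 0.7

#: inverse-Mills factors for the two outcome groups at the threshold
LAMBDA_DIABETIC = norm.pdf(THRESHOLD_Z) / norm.sf(THRESHOLD_Z)
LAMBDA_NON_DIABETIC = norm.pdf(THRESHOLD_Z) / norm.cdf(THRESHOLD_Z)
LAMBDA_SUM = LAMBDA_DIABETIC + LAMBDA_NON_DIABETIC  # ~= 1.7024


def truncnorm_group_means(rho: float) -> tuple[float, float]:
    """Expected mean z-score of a standardised variable with correlation
    ``rho`` to the latent outcome, within the above/below-threshold groups."""
    return rho * LAMBDA_DIABETIC, -rho * LAMBDA_NON_DIABETIC


def expected_interaction(corrs, weight_sd: float = 2.0) -> float:
    """Closed-form diabetes-by-age interaction implied by the group
    separations: half the difference between the age-2 and age-0 group mean
    gaps, each gap being corr * sd * (lambda1 + lambda0)."""
    gap0 = corrs[0] * weight_sd * LAMBDA_SUM
    gap2 = corrs[2] * weight_sd * LAMBDA_SUM
    return (gap2 - gap0) / 2.0


@pytest.fixture(scope="session")
def joint_gaussians():
    return {sid: cs.scenario_joint_gaussian(sid) for sid in "ABC"}


@pytest.fixture(scope="session")
def cohort_a(joint_gaussians):
    """One scenario-A cohort at the study's cohort size."""
    return cs.simulate_cohort(joint_gaussians["A"], 1000, np.random.SeedSequence([7]))


@pytest.fixture(scope="session")
def small_long(joint_gaussians):
    """Five-subject long table for dense-likelihood oracles."""
    cohort = cs.simulate_cohort(joint_gaussians["A"], 5, np.random.SeedSequence([11]))
    return cs.to_long(cohort)
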