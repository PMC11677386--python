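import pytest
from hypothesis import HealthCheck, settings

from musclecompare import CohortSpec, generate_cohort
from musclecompare.cohort import cohort_frame

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_cohort():
    """Study-sized synthetic cohort (n = 156), fixed seed."""
    return generate_cohort(CohortSpec(n=156), seed=7)


@pytest.fixture(scope="session")
def study_frame(study_cohort):
    return cohort_frame(study_cohort)


@pytest.fixture(scope="session")
def large_cohort():
    """Large cohort for distribution-level checks."""
    return generate_cohort(CohortSpec(n=5000), seed=11)


@pytest.fixture(scope="session")
def large_frame(large_cohort):
    return cohort_frame(large_cohort)
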