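import pytest
from hypothesis import HealthCheck, settings

from mesodose import (
    CohortSpec,
    build_rate_set,
    generate_bodyweight_table,
    generate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rate_set():
    """Rate set built from the published defaults and contact means."""
    return build_rate_set()


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic synthetic cohort for structural tests."""
    return generate_cohort(CohortSpec(n_growers=40, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """The default synthetic cohort at n = 500 for recovery checks."""
    return generate_cohort(CohortSpec(n_growers=500, seed=2024))


@pytest.fixture(scope="session")
def lookup_table():
    return generate_bodyweight_table("median_lookup")


@pytest.fixture(scope="session")
def weighted_table():
    return generate_bodyweight_table("weighted_sample", seed=5)
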