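import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A moderately sized synthetic cohort shared across read-only tests."""
    from efhs.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(n_participants=400, n_nonenrolled=300, seed=11)
    return cfg, generate_cohort(cfg)
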