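import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome():
    from mmcsig.simulate import simulate_genome

    return simulate_genome(100_000, seed=123)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """A small error-free cohort with fixed depth, for exact recovery tests."""
    from mmcsig.simulate import SimConfig, simulate_cohort

    config = SimConfig(
        seed=42,
        genome_length=300_000,
        n_strains=4,
        n_deletions_per_strain=6,
        n_snvs_per_strain=8,
        deletion_size_dist=("uniform", {"low": 5, "high": 300}),
        error_rate=0.0,
        fixed_depth=True,
        track_breakpoint=150_001,
    )
    return simulate_cohort(config)
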