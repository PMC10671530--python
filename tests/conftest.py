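import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from allelecall.simulate import SimulationConfig, fixture_suite, simulate


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down locus so multi-seed sweeps stay fast."""
    base = dict(
        seed=0,
        five_prime_len=300,
        exon_lens=(150, 150),
        intron_lens=(120,),
        three_prime_len=80,
        baseline_len=220,
        n_hybrid_alleles=4,
        members_per_allele=2,
        breakpoints_per_allele=1,
        derived_per_region={"five_prime": 1, "exon": 1},
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture(scope="session")
def small_sim():
    """One deterministic small simulated locus with allelets."""
    return simulate(small_config(seed=11, n_allelets=1))


@pytest.fixture(scope="session")
def default_sim():
    """The generator's default study conditions (rice-like locus)."""
    return simulate(SimulationConfig(seed=2, n_allelets=1))
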