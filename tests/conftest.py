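"""Shared fixtures: small seeded synthetic communities reused across tests."""

import pytest
from hypothesis import HealthCheck, settings

from magprof import synthetic

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_genomes() -> dict[str, str]:
    """Five independent 30 kb genomes."""
    specs = [
        synthetic.GenomeSpec(f"s{i}", 30_000, 0.40 + 0.04 * i,
                             synthetic.default_lineage(i))
        for i in range(5)
    ]
    return synthetic.generate_genomes(specs, 42)


@pytest.fixture(scope="session")
def small_cohort(small_genomes):
    """20 + 20 cohort over five species with one planted +2 log2 effect."""
    design = synthetic.CommunityDesign(
        n_samples_per_group=20,
        base_abundances={s: 1.0 for s in small_genomes},
        planted_effects={"s0": 2.0},
        noise_sigma=0.5,
        seed=7,
    )
    return synthetic.simulate_counts(design, small_genomes, 150, 100_000)


@pytest.fixture
def rel_matrix(small_cohort, small_genomes):
    from magprof import abundance as ab

    lengths = {s: len(g) for s, g in small_genomes.items()}
    depths = ab.depth_table(small_cohort.counts, 150, lengths)
    return ab.relative_abundance(depths)
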