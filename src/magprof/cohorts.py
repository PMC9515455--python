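"""Reference study designs: the cohort-scale conditions the package is validated on.

These generators pin down, in one place, the benchmark communities used by
the validation suite and the acceptance script: a MAG-quality survey with the
published per-tier counts of a 1,750-MAG gut catalogue, a species-recovery
benchmark with known ancestor membership, and a case/control cohort at the
scale of a 40-vs-37 preeclampsia study (~400 species, ~40 differentially
abundant).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic

#: published per-tier MAG counts of the 1,750-MAG survey: high, medium, low
MAG_SURVEY_TIER_COUNTS = (1042, 663, 45)


def mimag_survey_quality(
    rng_seed: int = 0, tier_counts: tuple[int, int, int] = MAG_SURVEY_TIER_COUNTS
) -> pd.DataFrame:
    """Per-MAG completeness/contamination table with given per-tier counts.

    Values are drawn uniformly inside each tier's defining region: high
    (completeness >= 90, contamination < 5), medium (70-90, contamination
    < 5, QS >= 60) and low (50-70), so re-classifying the table must
    reproduce the input tier composition.
    """
    rng = np.random.default_rng(rng_seed)
    n_high, n_med, n_low = tier_counts
    rows = []
    for _ in range(n_high):
        rows.append((float(rng.uniform(90, 100)), float(rng.uniform(0, 5))))
    for _ in range(n_med):
        comp = float(rng.uniform(70, 90))
        # stay inside both the contamination (<5) and QS (>=60) constraints
        cont_max = min(5.0, (comp - 60.0) / 5.0)
        rows.append((comp, float(rng.uniform(0, cont_max))))
    for _ in range(n_low):
        rows.append((float(rng.uniform(50, 70)), float(rng.uniform(5, 10))))
    frame = pd.DataFrame(rows, columns=["completeness", "contamination"])
    frame.index = [f"MAG{i:04d}" for i in range(len(frame))]
    frame.index.name = "mag_id"
    return frame


def species_recovery_community(
    rng_seed: int = 0,
    n_ancestors: int = 8,
    n_mags: int = 30,
    genome_length: int = 100_000,
    max_divergence: float = 0.01,
) -> tuple[dict[str, str], pd.Series]:
    """MAG genomes from known ancestors for dereplication benchmarking.

    ``n_mags`` genomes are spread round-robin over ``n_ancestors``
    independent ancestors, each derived at divergence Uniform(0.002,
    ``max_divergence``) so that within-species pairwise divergence stays
    ~<= 2% (ANI >= ~98%) while between-species identity is far below any
    species threshold. Returns (mag genomes, truth mapping mag -> ancestor).
    """
    rng = np.random.default_rng(rng_seed)
    specs = [
        synthetic.GenomeSpec(f"anc{i}", genome_length, float(rng.uniform(0.4, 0.55)),
                             synthetic.default_lineage(i))
        for i in range(n_ancestors)
    ]
    ancestors = synthetic.generate_genomes(specs, int(rng.integers(0, 2**31 - 1)))
    mags: dict[str, str] = {}
    truth: dict[str, str] = {}
    for m in range(n_mags):
        anc = specs[m % n_ancestors]
        mag_id = f"{anc.species_id}.m{m // n_ancestors}"
        mags[mag_id] = synthetic.generate_genome(
            synthetic.GenomeSpec(
                mag_id, genome_length, anc.gc_target, anc.lineage,
                parent_id=anc.species_id,
                divergence=float(rng.uniform(0.002, max_divergence)),
            ),
            int(rng.integers(0, 2**31 - 1)),
            ancestors,
        )
        truth[mag_id] = anc.species_id
    return mags, pd.Series(truth, name="ancestor")


def case_control_design(
    seed: int,
    n_case: int = 40,
    n_control: int = 37,
    n_species: int = 400,
    n_planted: int = 40,
    effect_range: tuple[float, float] = (1.0, 2.0),
    noise_sigma: float = 1.0,
) -> tuple[synthetic.CommunityDesign, dict[str, int]]:
    """PE/HC cohort design at published-study scale.

    ~10% of species carry planted log2 effects with magnitudes drawn from
    ``effect_range``, half enriched in each group, over a log-normal baseline
    community. Group sizes are asymmetric (40 vs 37) like the study cohort.
    ``n_control`` may differ from ``n_case``; the generator pads the smaller
    group by truncation of the symmetric design.

    Returns the design plus genome lengths (uniform 2-4 Mb scaled down 20x).
    """
    rng = np.random.default_rng(seed)
    species = [f"sp{i:04d}" for i in range(n_species)]
    base = {s: float(rng.lognormal(0.0, 1.0)) for s in species}
    planted_idx = rng.choice(n_species, size=n_planted, replace=False)
    effects = {}
    for rank, idx in enumerate(sorted(planted_idx)):
        mag = float(rng.uniform(*effect_range))
        effects[species[idx]] = mag if rank % 2 == 0 else -mag
    design = synthetic.CommunityDesign(
        n_samples_per_group=max(n_case, n_control),
        base_abundances=base,
        planted_effects=effects,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    lengths = {s: int(rng.uniform(100_000, 200_000)) for s in species}
    return design, lengths


def simulate_case_control(
    seed: int,
    n_case: int = 40,
    n_control: int = 37,
    reads_per_sample: int = 100_000,
    **design_kwargs,
) -> synthetic.SimulatedCounts:
    """Simulate the asymmetric case/control cohort (counts + truth)."""
    design, lengths = case_control_design(
        seed, n_case=n_case, n_control=n_control, **design_kwargs
    )
    sim = synthetic.simulate_counts(design, lengths, 150, reads_per_sample)
    keep = [f"PE{i:03d}" for i in range(n_case)] + [f"HC{i:03d}" for i in range(n_control)]
    return synthetic.SimulatedCounts(
        counts=sim.counts.loc[keep],
        labels=sim.labels.loc[keep],
        true_proportions=sim.true_proportions.loc[keep],
        read_length=sim.read_length,
    )
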