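"""Seeded synthetic gut-community generator with known ground truth.

The generator emulates, at desk scale, every external input of the MAG
analysis chain: genomes with controlled pairwise divergence (hence controlled
ANI), per-sample bins with target completeness/contamination, multinomial
mapped-read counts with planted case/control (PE/HC) log2 effects, and a
Prodigal/BlastKOALA-style gene/KO hit catalogue with a KO->module map.

All randomness flows through ``numpy.random.default_rng`` seeded explicitly,
so every artefact is bit-reproducible.

Divergence between genomes is substitution-only (no indels): a child genome
at substitution rate ``d`` from its parent has expected Hamming fraction
``d`` and expected ANI ``100*(1-d)``, which keeps the dereplication ground
truth analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqs import decode, encode

GROUPS = ("PE", "HC")


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for one synthetic genome.

    ``parent_id``/``divergence`` place the genome at a controlled substitution
    distance from an ancestor, which fixes its expected ANI at
    ``100*(1-divergence)``.
    """

    species_id: str
    length: int
    gc_target: float = 0.45
    lineage: str = "d__;p__;c__;o__;f__;g__;s__"
    parent_id: str | None = None
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"length must be positive, got {self.length}")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError(f"gc_target must be in [0,1], got {self.gc_target}")
        if self.divergence < 0:
            raise ValueError(f"divergence must be >= 0, got {self.divergence}")
        if len(self.lineage.split(";")) != 7:
            raise ValueError(f"lineage must have 7 rank fields: {self.lineage!r}")


@dataclass
class CommunityDesign:
    """Study design for a two-group (PE vs HC) synthetic cohort.

    ``planted_effects`` are log2 fold changes of PE over HC mean abundance;
    ``noise_sigma`` is the standard deviation (log2 scale) of the per-sample
    log-normal abundance perturbation.
    """

    n_samples_per_group: int
    base_abundances: dict[str, float]
    planted_effects: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 1.0
    group_labels: tuple[str, str] = GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")
        if any(a <= 0 for a in self.base_abundances.values()):
            raise ValueError("base_abundances must all be > 0")
        missing = set(self.planted_effects) - set(self.base_abundances)
        if missing:
            raise ValueError(f"planted species not in community: {sorted(missing)}")


def generate_genome(
    spec: GenomeSpec,
    rng_seed: int,
    genomes: Mapping[str, str] | None = None,
) -> str:
    """Generate one genome, de novo or by substitution from ``spec.parent_id``.

    De-novo genomes draw i.i.d. bases with P(G or C) = ``gc_target``. Derived
    genomes copy the parent and substitute a Binomial(length, divergence)
    number of distinct sites, each to a uniformly chosen different base, so
    Hamming distance / length concentrates at ``divergence``.
    """
    rng = np.random.default_rng(rng_seed)
    if spec.parent_id is None:
        gc = spec.gc_target
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        codes = rng.choice(4, size=spec.length, p=p).astype(np.uint8)
        return decode(codes)
    if genomes is None or spec.parent_id not in genomes:
        raise KeyError(f"unknown parent_id {spec.parent_id!r}")
    parent = encode(genomes[spec.parent_id])
    if len(parent) != spec.length:
        parent = parent[: spec.length]
        if len(parent) < spec.length:
            raise ValueError("parent genome shorter than requested length")
    child = parent.copy()
    n_sub = rng.binomial(spec.length, spec.divergence)
    if n_sub:
        pos = rng.choice(spec.length, size=n_sub, replace=False)
        shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
        child[pos] = (child[pos] + shift) % 4
    return decode(child)


def generate_genomes(specs: Sequence[GenomeSpec], rng_seed: int) -> dict[str, str]:
    """Resolve a list of specs in order; parents must precede children."""
    rng = np.random.default_rng(rng_seed)
    genomes: dict[str, str] = {}
    for spec in specs:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        genomes[spec.species_id] = generate_genome(spec, sub_seed, genomes)
    return genomes


def make_species_genomes(
    n_species: int,
    mags_per_species: int,
    length: int,
    within_divergence: float,
    rng_seed: int,
    gc_range: tuple[float, float] = (0.35, 0.60),
) -> tuple[dict[str, str], dict[str, str], pd.Series]:
    """Ancestor genomes plus derived MAG-level genomes with known membership.

    Ancestors are generated independently (pairwise ANI far below any species
    threshold); each species contributes ``mags_per_species`` derived genomes
    at divergence Uniform(0, within_divergence) from its ancestor. Returns
    ``(ancestors, mag_genomes, truth)`` where ``truth`` maps mag_id to its
    source species_id.
    """
    rng = np.random.default_rng(rng_seed)
    specs: list[GenomeSpec] = []
    for i in range(n_species):
        gc = rng.uniform(*gc_range)
        lineage = default_lineage(i)
        specs.append(GenomeSpec(f"sp{i:03d}", length, gc, lineage))
    ancestors = generate_genomes(specs, int(rng.integers(0, 2**31 - 1)))

    mag_specs: list[GenomeSpec] = []
    truth: dict[str, str] = {}
    for spec in specs:
        for j in range(mags_per_species):
            d = float(rng.uniform(0, within_divergence))
            mag_id = f"{spec.species_id}.m{j}"
            mag_specs.append(
                GenomeSpec(mag_id, length, spec.gc_target, spec.lineage,
                           parent_id=spec.species_id, divergence=d)
            )
            truth[mag_id] = spec.species_id
    pool = dict(ancestors)
    rng2 = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
    mags: dict[str, str] = {}
    for ms in mag_specs:
        mags[ms.species_id] = generate_genome(ms, int(rng2.integers(0, 2**31 - 1)), pool)
    return ancestors, mags, pd.Series(truth, name="species_id")


def default_lineage(i: int, n_phyla: int = 4, n_families: int = 8) -> str:
    """Deterministic 7-rank GTDB-style lineage for synthetic species ``i``."""
    p = i % n_phyla
    f = i % n_families
    return (
        f"d__Bacteria;p__P{p:02d};c__C{p:02d};o__O{f:02d};"
        f"f__F{f:02d};g__G{i:03d};s__S{i:03d}"
    )


@dataclass
class BinFragments:
    """Contigs of one synthetic bin plus its base-count ground truth."""

    native: list[str]
    contaminant: list[str]
    source_length: int

    @property
    def contigs(self) -> list[str]:
        return self.native + self.contaminant

    @property
    def native_bases(self) -> int:
        return sum(len(c) for c in self.native)

    @property
    def contaminant_bases(self) -> int:
        return sum(len(c) for c in self.contaminant)

    @property
    def realized_completeness(self) -> float:
        return 100.0 * self.native_bases / self.source_length

    @property
    def realized_contamination(self) -> float:
        return 100.0 * self.contaminant_bases / max(self.native_bases, 1)


def _tile(length: int, min_contig: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Split [0, length) into windows each >= min_contig (last absorbs remainder)."""
    cap = max(min_contig, length // 60)
    bounds: list[tuple[int, int]] = []
    start = 0
    while start < length:
        size = int(rng.integers(min_contig, cap + 1))
        end = min(start + size, length)
        if length - end < min_contig:
            end = length
        bounds.append((start, end))
        start = end
    return bounds


def fragment_to_bin(
    genome: str,
    target_completeness: float,
    contaminant_pool: Sequence[str],
    target_contamination: float,
    min_contig: int = 2000,
    rng_seed: int = 0,
) -> BinFragments:
    """Fragment a genome into a bin with target completeness/contamination.

    The genome is tiled into contigs of at least ``min_contig`` bp; a random
    subset totalling ~``target_completeness`` % of the genome is retained, and
    contaminant contigs cut from ``contaminant_pool`` are appended until
    contaminant/native bases reach ~``target_contamination`` %. Both realized
    values land within ±2 percentage points of target provided contig sizes
    are small relative to the genome (they are capped at length/60).
    """
    if not 0 < target_completeness <= 100:
        raise ValueError("target_completeness must be in (0, 100]")
    if target_contamination < 0:
        raise ValueError("target_contamination must be >= 0")
    if len(genome) < min_contig:
        raise ValueError(
            f"genome ({len(genome)} bp) shorter than min_contig ({min_contig} bp)"
        )
    rng = np.random.default_rng(rng_seed)
    bounds = _tile(len(genome), min_contig, rng)
    order = rng.permutation(len(bounds))
    target_bases = target_completeness / 100.0 * len(genome)
    native: list[str] = []
    total = 0
    for idx in order:
        s, e = bounds[int(idx)]
        size = e - s
        if total >= target_bases:
            break
        # keep the contig only if it moves the total closer to the target
        if abs(total + size - target_bases) <= abs(total - target_bases):
            native.append(genome[s:e])
            total += size
    if not native:  # degenerate tiny targets: keep the closest single contig
        s, e = bounds[int(order[0])]
        native.append(genome[s:e])
        total = e - s

    contaminant: list[str] = []
    if target_contamination > 0:
        if not contaminant_pool:
            raise ValueError("target_contamination > 0 but contaminant_pool is empty")
        target_cont_bases = target_contamination / 100.0 * total
        cont_total = 0
        while cont_total < target_cont_bases:
            src = contaminant_pool[int(rng.integers(len(contaminant_pool)))]
            if len(src) < min_contig:
                continue
            cap = max(min_contig, len(src) // 60)
            size = int(rng.integers(min_contig, cap + 1))
            start = int(rng.integers(0, len(src) - size + 1))
            if abs(cont_total + size - target_cont_bases) > abs(cont_total - target_cont_bases):
                break
            contaminant.append(src[start : start + size])
            cont_total += size
    return BinFragments(native, contaminant, len(genome))


@dataclass
class SimulatedCounts:
    """Mapped-read counts with the abundance ground truth that generated them."""

    counts: pd.DataFrame          # samples x species, integer reads
    labels: pd.Series             # sample_id -> group
    true_proportions: pd.DataFrame  # samples x species, depth-scale truth
    read_length: int


def simulate_counts(
    design: CommunityDesign,
    genomes: Mapping[str, str] | Mapping[str, int],
    read_length: int = 150,
    reads_per_sample: int = 100_000,
) -> SimulatedCounts:
    """Multinomial mapped-read counts under the community design.

    Per sample, species abundance on the log2 scale is
    ``log2(base) + effect*[group==PE] + Normal(0, noise_sigma)``; reads are
    then drawn multinomially with probability proportional to
    ``abundance * genome_length`` (longer genomes soak up more reads, which
    the depth normalisation downstream removes). ``true_proportions`` stores
    the length-free abundance fractions that depth-based profiling estimates.
    """
    if reads_per_sample <= 0:
        raise ValueError("reads_per_sample must be > 0")
    species = list(design.base_abundances)
    missing = [s for s in species if s not in genomes]
    if missing:
        raise KeyError(f"species without genomes: {missing}")
    lengths = np.array(
        [len(g) if isinstance(g := genomes[s], str) else int(g) for s in species],
        dtype=float,
    )
    base = np.log2(np.array([design.base_abundances[s] for s in species]))
    effect = np.array([design.planted_effects.get(s, 0.0) for s in species])
    rng = np.random.default_rng(design.seed)
    case, control = design.group_labels
    sample_ids, groups, count_rows, true_rows = [], [], [], []
    for g_idx, group in enumerate((case, control)):
        for j in range(design.n_samples_per_group):
            log2a = base + (effect if group == case else 0.0)
            log2a = log2a + rng.normal(0.0, design.noise_sigma, size=len(species))
            a = np.exp2(log2a)
            true_rows.append(a / a.sum())
            p = a * lengths
            count_rows.append(rng.multinomial(reads_per_sample, p / p.sum()))
            sample_ids.append(f"{group}{j:03d}")
            groups.append(group)
    counts = pd.DataFrame(count_rows, index=sample_ids, columns=species)
    truth = pd.DataFrame(true_rows, index=sample_ids, columns=species)
    labels = pd.Series(groups, index=sample_ids, name="group")
    return SimulatedCounts(counts, labels, truth, read_length)


@dataclass
class GeneCatalog:
    """Synthetic gene/KO annotation tables.

    ``genes``: gene_id, species_id, ko_true, copy. ``hits``: gene_id, ko,
    e_value, coverage (spanning both sides of the best-hit filter).
    ``ko_to_category``: category_id, ko, level.
    """

    genes: pd.DataFrame
    hits: pd.DataFrame
    ko_to_category: pd.DataFrame


def generate_gene_catalog(
    species_ids: Sequence[str],
    n_kos: int,
    genes_per_genome: int,
    rng_seed: int,
    planted_kos: Mapping[str, Sequence[str]] | None = None,
    frac_subthreshold: float = 0.10,
    n_modules: int = 12,
    kos_per_module: int = 5,
) -> GeneCatalog:
    """Emulate Prodigal + BlastKOALA outputs for a set of species genomes.

    Each species carries ``genes_per_genome`` background genes with uniformly
    drawn true KOs, plus one extra gene per planted KO it carries
    (``planted_kos`` maps KO -> carrier species). A fraction
    ``frac_subthreshold`` of primary hits is generated just outside the
    best-hit filter (e-value >= 1e-10 or coverage <= 0.5) so the filter is
    exercised; passing genes may also receive a strictly worse decoy hit to
    exercise best-hit selection. Modules sample KOs with replacement across
    modules, so categories may overlap.
    """
    if n_kos <= 0:
        raise ValueError("n_kos must be > 0")
    rng = np.random.default_rng(rng_seed)
    planted_kos = dict(planted_kos or {})
    kos = [f"K{j:05d}" for j in range(n_kos)]
    background = [k for k in kos if k not in planted_kos]

    gene_rows: list[tuple[str, str, str, int]] = []
    for sp in species_ids:
        for j in range(genes_per_genome):
            ko = background[int(rng.integers(len(background)))] if background else kos[0]
            gene_rows.append((f"{sp}.g{j:04d}", sp, ko, 1))
    for ko, carriers in planted_kos.items():
        for sp in carriers:
            if sp not in species_ids:
                raise KeyError(f"planted KO carrier {sp!r} not in species set")
            gene_rows.append((f"{sp}.{ko}", sp, ko, 1))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "species_id", "ko_true", "copy"])

    hit_rows: list[tuple[str, str, float, float]] = []
    for gene_id, _sp, ko_true, _copy in gene_rows:
        good = rng.random() >= frac_subthreshold
        if good:
            e = 10.0 ** rng.uniform(-40, -12)
            cov = rng.uniform(0.55, 0.95)
        elif rng.random() < 0.5:  # fail on e-value
            e = 10.0 ** rng.uniform(-9.5, -5)
            cov = rng.uniform(0.55, 0.95)
        else:  # fail on coverage
            e = 10.0 ** rng.uniform(-40, -12)
            cov = rng.uniform(0.10, 0.50)
        hit_rows.append((gene_id, ko_true, e, cov))
        if good and rng.random() < 0.4:
            decoy_ko = kos[int(rng.integers(n_kos))]
            if decoy_ko != ko_true:
                hit_rows.append(
                    (gene_id, decoy_ko, e * 10.0 ** rng.uniform(1, 6),
                     float(rng.uniform(0.55, 0.95)))
                )
    hits = pd.DataFrame(hit_rows, columns=["gene_id", "ko", "e_value", "coverage"])

    cat_rows: list[tuple[str, str, str]] = []
    planted_list = list(planted_kos)
    for m in range(n_modules):
        module_id = f"M{m:05d}"
        members = set(rng.choice(len(kos), size=min(kos_per_module, n_kos), replace=False))
        member_kos = {kos[int(i)] for i in members}
        if planted_list:  # guarantee each planted KO sits in >= 1 module
            member_kos.add(planted_list[m % len(planted_list)])
        for ko in sorted(member_kos):
            cat_rows.append((module_id, ko, "module"))
    ko_to_category = pd.DataFrame(cat_rows, columns=["category_id", "ko", "level"])
    return GeneCatalog(genes, hits, ko_to_category)
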