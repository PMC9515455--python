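"""End-to-end orchestration: fixtures -> refine -> derep -> profile -> functions -> stats -> classify.

Each stage reads and writes plain TSV/FASTA under the configured output
directory, skips itself when its outputs are newer than its inputs (a
``force`` flag overrides), and records input digests, parameters and seeds in
``manifest.json``. All stage randomness derives from the single configured
seed, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import binning, classify, dereplication, functions, stats, synthetic
from .io import file_digest, params_hash, read_tsv, write_tsv
from .seqs import read_fasta, write_fasta

logger = logging.getLogger(__name__)

STAGES = ("fixtures", "refine", "derep", "profile", "functions", "stats", "classify")


@dataclass
class PipelineConfig:
    """One audited record of every threshold the chain uses.

    Defaults are the study-scale values (200 kb size filter, QS >= 60,
    95% ANI, 1e-10 / 50% KO filter, 1,000 permutations and trees); the
    fixture generator writes a config with the size filter rescaled to its
    desk-scale genomes.
    """

    fixtures_dir: str = "fixtures"
    out_dir: str = "out"
    seed: int = 0
    read_length: int = 150
    depth_tol: float = 0.10
    gc_tol: float = 0.02
    min_total_size: int = 200_000
    qs_min: float = 60.0
    ani_threshold: float = 95.0
    sketch_k: int = 21
    sketch_size: int = 5000
    ko_evalue: float = 1e-10
    ko_cov: float = 0.5
    n_perm: int = 1000
    n_trees: int = 1000
    alpha: float = 0.05
    n_rarefaction: int = 30
    write_ani: bool = False
    case_label: str = "PE"

    def __post_init__(self) -> None:
        checks = [
            (0 < self.depth_tol <= 1, "depth_tol in (0,1]"),
            (0 < self.gc_tol <= 1, "gc_tol in (0,1]"),
            (self.min_total_size >= 0, "min_total_size >= 0"),
            (0 <= self.qs_min <= 100, "qs_min in [0,100]"),
            (0 < self.ani_threshold < 100, "ani_threshold in (0,100)"),
            (self.ko_evalue > 0, "ko_evalue > 0"),
            (0 < self.ko_cov < 1, "ko_cov in (0,1)"),
            (self.n_perm >= 1, "n_perm >= 1"),
            (self.n_trees >= 1, "n_trees >= 1"),
            (0 < self.alpha < 1, "alpha in (0,1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"config violates {msg}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def make_fixtures(
    fixtures_dir: str | Path,
    seed: int = 0,
    n_species: int = 10,
    mags_per_species: int = 3,
    n_samples_per_group: int = 6,
    genome_length: int = 60_000,
    reads_per_sample: int = 50_000,
    within_divergence: float = 0.015,
    split_prob: float = 0.35,
    min_contig: int = 2000,
    n_kos: int = 80,
    genes_per_genome: int = 25,
    n_planted_species: int = 4,
    planted_effect: float = 1.5,
    n_planted_kos: int = 4,
    noise_sigma: float = 1.0,
    read_length: int = 150,
) -> PipelineConfig:
    """Write a complete synthetic input set plus a matching config.yaml.

    Emulates, per species, several per-sample MAGs derived from a common
    ancestor at small divergence, fragments them into raw bins (occasionally
    split in two to exercise merging), and generates counts, labels, gene/KO
    tables with planted PE/HC effects. The bin size filter in the emitted
    config is rescaled to ~8% of the genome length, the same ratio the
    200 kb rule bears to a typical 2.5 Mb gut genome.
    """
    out = Path(fixtures_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    specs = [
        synthetic.GenomeSpec(
            f"sp{i:03d}", genome_length, float(rng.uniform(0.38, 0.58)),
            synthetic.default_lineage(i),
        )
        for i in range(n_species)
    ]
    genomes = synthetic.generate_genomes(specs, int(rng.integers(0, 2**31 - 1)))
    species = pd.DataFrame(
        {
            "species_id": [s.species_id for s in specs],
            "lineage": [s.lineage for s in specs],
            "genome_length": [len(genomes[s.species_id]) for s in specs],
        }
    ).set_index("species_id")
    write_tsv(out / "species.tsv", species, stage="fixtures")

    planted = {}
    for i in range(min(n_planted_species, n_species)):
        planted[specs[i].species_id] = planted_effect if i % 2 == 0 else -planted_effect
    design = synthetic.CommunityDesign(
        n_samples_per_group=n_samples_per_group,
        base_abundances={s.species_id: float(rng.lognormal(0.0, 1.0)) for s in specs},
        planted_effects=planted,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    sim = synthetic.simulate_counts(design, genomes, read_length, reads_per_sample)
    write_tsv(out / "counts.tsv", sim.counts, stage="fixtures")
    write_tsv(out / "true_proportions.tsv", sim.true_proportions, stage="fixtures")
    write_tsv(out / "labels.tsv", sim.labels.to_frame(), stage="fixtures")
    write_tsv(
        out / "planted_effects.tsv",
        pd.Series(planted, name="log2fc").rename_axis("species_id").to_frame(),
        stage="fixtures",
    )

    samples = list(sim.counts.index)
    quality_rows, tax_rows, reads_rows = [], [], []
    bin_counter: dict[str, int] = {s: 0 for s in samples}
    for spec in specs:
        hosts = rng.choice(samples, size=min(mags_per_species, len(samples)), replace=False)
        for sample in hosts:
            child = synthetic.generate_genome(
                synthetic.GenomeSpec(
                    f"{spec.species_id}@{sample}", genome_length, spec.gc_target,
                    spec.lineage, parent_id=spec.species_id,
                    divergence=float(rng.uniform(0.0, within_divergence)),
                ),
                int(rng.integers(0, 2**31 - 1)),
                genomes,
            )
            pool = [genomes[s.species_id] for s in specs if s.species_id != spec.species_id]
            frags = synthetic.fragment_to_bin(
                child,
                target_completeness=float(rng.uniform(72, 99)),
                contaminant_pool=pool,
                target_contamination=float(rng.uniform(0, 4)),
                min_contig=min_contig,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
            depth = (
                sim.counts.loc[sample, spec.species_id] * read_length / genome_length
            )
            if rng.random() < split_prob and len(frags.native) >= 4:
                halves = [frags.native[0::2], frags.native[1::2]]
                extras = [frags.contaminant, []]
            else:
                halves = [frags.native]
                extras = [frags.contaminant]
            for part_native, part_cont in zip(halves, extras):
                bin_id = f"{sample}.b{bin_counter[sample]:03d}"
                bin_counter[sample] += 1
                contigs = part_native + part_cont
                write_fasta(
                    out / "bins" / sample / f"{bin_id}.fasta",
                    {f"{bin_id}.c{i}": c for i, c in enumerate(contigs)},
                )
                native_bp = sum(len(c) for c in part_native)
                cont_bp = sum(len(c) for c in part_cont)
                quality_rows.append(
                    (bin_id, sample, 100.0 * native_bp / genome_length,
                     100.0 * cont_bp / max(native_bp, 1))
                )
                tax_rows.append((bin_id, spec.lineage))
                total_bp = native_bp + cont_bp
                reads_rows.append(
                    (bin_id, sample, int(round(depth * total_bp / read_length)))
                )
    write_tsv(
        out / "quality.tsv",
        pd.DataFrame(quality_rows,
                     columns=["bin_id", "sample_id", "completeness", "contamination"]
                     ).set_index("bin_id"),
        stage="fixtures",
    )
    write_tsv(
        out / "taxonomy.tsv",
        pd.DataFrame(tax_rows, columns=["bin_id", "lineage"]).set_index("bin_id"),
        stage="fixtures",
    )
    write_tsv(
        out / "bin_reads.tsv",
        pd.DataFrame(reads_rows, columns=["bin_id", "sample_id", "mapped_reads"]
                     ).set_index("bin_id"),
        stage="fixtures",
    )

    pe_enriched = [s for s, e in planted.items() if e > 0]
    planted_kos = {
        f"K{90000 + i:05d}": pe_enriched for i in range(n_planted_kos) if pe_enriched
    }
    catalog = synthetic.generate_gene_catalog(
        [s.species_id for s in specs],
        n_kos=n_kos,
        genes_per_genome=genes_per_genome,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        planted_kos=planted_kos,
    )
    write_tsv(out / "genes.tsv", catalog.genes.set_index("gene_id"), stage="fixtures")
    write_tsv(out / "hits.tsv", catalog.hits.set_index("gene_id"), stage="fixtures")
    write_tsv(out / "ko_map.tsv", catalog.ko_to_category.set_index("category_id"),
              stage="fixtures")

    config = PipelineConfig(
        fixtures_dir=str(out),
        out_dir=str(out.parent / "out" if out.name != "." else Path("out")),
        seed=seed,
        read_length=read_length,
        min_total_size=int(genome_length * 0.08),
    )
    config.to_yaml(out / "config.yaml")
    return config


# ---------------------------------------------------------------- stages


def _load_bins(cfg: PipelineConfig) -> dict[str, list[binning.Bin]]:
    fx = Path(cfg.fixtures_dir)
    quality = read_tsv(fx / "quality.tsv")
    taxonomy = read_tsv(fx / "taxonomy.tsv")
    reads = read_tsv(fx / "bin_reads.tsv")
    per_sample: dict[str, list[binning.Bin]] = {}
    for bin_id, row in quality.iterrows():
        sample = row["sample_id"]
        fasta = fx / "bins" / sample / f"{bin_id}.fasta"
        if not fasta.exists():
            raise FileNotFoundError(f"bin FASTA missing for {bin_id}: {fasta}")
        contigs = list(read_fasta(fasta).values())
        total_len = sum(len(c) for c in contigs)
        depth = binning.compute_depth(
            int(reads.loc[bin_id, "mapped_reads"]), cfg.read_length, total_len
        )
        b = binning.Bin(
            bin_id=str(bin_id),
            sample_id=sample,
            contigs=contigs,
            depth=depth,
            lineage=str(taxonomy.loc[bin_id, "lineage"]),
            quality=binning.QualityRecord(
                float(row["completeness"]), float(row["contamination"])
            ),
        )
        per_sample.setdefault(sample, []).append(b)
    return per_sample


def stage_refine(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    per_sample = _load_bins(cfg)
    all_refined: list[binning.Bin] = []
    eligible: list[binning.Bin] = []
    audits = []
    for sample in sorted(per_sample):
        raw = per_sample[sample]
        sized = [b for b in raw if b.total_length > cfg.min_total_size]
        dropped = [b.bin_id for b in raw if b.total_length <= cfg.min_total_size]
        if dropped:
            logger.info("%s: %d bins below size filter", sample, len(dropped))
        merged = binning.merge_bins(sized, depth_tol=cfg.depth_tol, gc_tol=cfg.gc_tol)
        result = binning.filter_bins(merged, min_total_size=cfg.min_total_size,
                                     qs_min=cfg.qs_min)
        all_refined.extend(result.retained)
        eligible.extend(result.derep_eligible)
        audits.append(result.audit)
    manifest = binning.refined_manifest(all_refined)
    eligible_ids = {b.bin_id for b in eligible}
    manifest["derep_eligible"] = manifest["bin_id"].isin(eligible_ids)
    write_tsv(out / "refined_manifest.tsv", manifest.set_index("bin_id"),
              stage="refine", params={"depth_tol": cfg.depth_tol, "gc_tol": cfg.gc_tol,
                                      "min_total_size": cfg.min_total_size,
                                      "qs_min": cfg.qs_min})
    write_tsv(out / "refine_audit.tsv", pd.concat(audits).set_index("bin_id"),
              stage="refine")
    for b in eligible:
        write_fasta(out / "refined_bins" / f"{b.bin_id}.fasta",
                    {f"{b.bin_id}.c{i}": c for i, c in enumerate(b.contigs)})


def stage_derep(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    manifest = read_tsv(out / "refined_manifest.tsv")
    eligible = manifest[manifest["derep_eligible"]]
    mags = []
    sketches = {}
    for bin_id, row in eligible.iterrows():
        seqs = read_fasta(out / "refined_bins" / f"{bin_id}.fasta")
        genome = "".join(seqs.values())
        sk = dereplication.sketch(genome, k=cfg.sketch_k, sketch_size=cfg.sketch_size)
        sketches[str(bin_id)] = sk
        mags.append(
            dereplication.MagRecord(
                mag_id=str(bin_id), sketch=sk, qs=float(row["qs"]),
                total_length=int(row["total_length"]), lineage=str(row["lineage"]),
            )
        )
    clusters = dereplication.cluster_species(mags, ani_threshold=cfg.ani_threshold)
    table = pd.DataFrame(
        {
            "species_id": [c.species_id for c in clusters],
            "representative": [c.representative_mag_id for c in clusters],
            "n_members": [len(c.member_mag_ids) for c in clusters],
            "members": [",".join(c.member_mag_ids) for c in clusters],
            "lineage": [c.lineage for c in clusters],
        }
    ).set_index("species_id")
    write_tsv(out / "clusters.tsv", table, stage="derep",
              params={"ani_threshold": cfg.ani_threshold, "k": cfg.sketch_k,
                      "sketch_size": cfg.sketch_size})
    if cfg.write_ani and len(sketches) <= 100:
        write_tsv(out / "pairwise_ani.tsv", dereplication.ani_matrix(sketches),
                  stage="derep")


def _species_of_clusters(cfg: PipelineConfig) -> pd.Series:
    """Map cluster id -> source species_id via the species-rank lineage name."""
    out = Path(cfg.out_dir)
    clusters = read_tsv(out / "clusters.tsv")
    species = read_tsv(Path(cfg.fixtures_dir) / "species.tsv")
    sname_to_sp = {
        lin.split(";")[6].strip(): sp for sp, lin in species["lineage"].items()
    }
    mapping = {}
    for cid, row in clusters.iterrows():
        sname = str(row["lineage"]).split(";")[6].strip()
        if sname in sname_to_sp:
            mapping[cid] = sname_to_sp[sname]
        else:
            logger.warning("cluster %s has no matching source species (%s)", cid, sname)
    return pd.Series(mapping, name="species_id")


def stage_profile(cfg: PipelineConfig) -> None:
    fx, out = Path(cfg.fixtures_dir), Path(cfg.out_dir)
    counts = read_tsv(fx / "counts.tsv")
    species = read_tsv(fx / "species.tsv")
    labels = read_tsv(fx / "labels.tsv")["group"]
    mapped = _species_of_clusters(cfg)
    kept = [sp for sp in counts.columns if sp in set(mapped.values)]
    lost = set(counts.columns) - set(kept)
    if lost:
        logger.warning("counts for %d species not in the MAG catalogue dropped: %s",
                       len(lost), sorted(lost))
    depths = ab.depth_table(counts[kept], cfg.read_length,
                            species["genome_length"].to_dict())
    rel = ab.relative_abundance(depths)
    write_tsv(out / "species_abundance.tsv", rel.data, stage="profile",
              params={"read_length": cfg.read_length})
    lineages = species["lineage"].to_dict()
    for rank in ("phylum", "family", "genus"):
        rolled = ab.rollup_taxa(rel, lineages, rank)
        write_tsv(out / f"taxon_{rank}_abundance.tsv", rolled.data, stage="profile")
    div = pd.DataFrame(
        {
            "shannon": [ab.diversity_index(rel.data.loc[s], "shannon")
                        for s in rel.sample_ids],
            "simpson": [ab.diversity_index(rel.data.loc[s], "simpson")
                        for s in rel.sample_ids],
        },
        index=pd.Index(rel.sample_ids, name="sample_id"),
    )
    write_tsv(out / "diversity.tsv", div, stage="profile")
    rare = ab.rarefaction_curve(rel, labels, n_reps=cfg.n_rarefaction,
                                rng_seed=cfg.seed)
    write_tsv(out / "rarefaction.tsv", rare.set_index("group"), stage="profile",
              params={"n_reps": cfg.n_rarefaction, "seed": cfg.seed})


def stage_functions(cfg: PipelineConfig) -> None:
    fx, out = Path(cfg.fixtures_dir), Path(cfg.out_dir)
    rel_data = read_tsv(out / "species_abundance.tsv")
    rel = ab.AbundanceMatrix(rel_data, level="species", relative=True)
    genes = read_tsv(fx / "genes.tsv").reset_index()
    hits = read_tsv(fx / "hits.tsv").reset_index()
    ko_map = read_tsv(fx / "ko_map.tsv").reset_index()
    assignments = functions.assign_kos(hits, e_value_max=cfg.ko_evalue,
                                       coverage_min=cfg.ko_cov)
    present = genes["species_id"].isin(rel.feature_ids)
    gene_ab = functions.gene_abundance(rel, genes[present])
    kos = sorted(assignments.loc[assignments.index.isin(gene_ab.columns)].unique())
    ko_abund = functions.category_abundance(
        gene_ab, assignments, functions.ko_categories(kos), level="ko"
    )
    write_tsv(out / "ko_abundance.tsv", ko_abund.data, stage="functions",
              params={"e_value": cfg.ko_evalue, "coverage": cfg.ko_cov})
    mod_abund = functions.category_abundance(gene_ab, assignments, ko_map, level="module")
    write_tsv(out / "module_abundance.tsv", mod_abund.data, stage="functions")

    species_of_gene = genes.set_index("gene_id")["species_id"].to_dict()
    contrib_rows = []
    for module_id, kos_in_mod in ko_map.groupby("category_id")["ko"]:
        try:
            contrib = functions.species_contribution(
                set(kos_in_mod), gene_ab, assignments, species_of_gene
            )
        except ValueError:
            continue
        for sp, share in contrib.mean.items():
            contrib_rows.append((module_id, sp, share))
    write_tsv(
        out / "module_species_contribution.tsv",
        pd.DataFrame(contrib_rows, columns=["category_id", "species_id", "mean_share"]
                     ).set_index("category_id"),
        stage="functions",
    )


def stage_stats(cfg: PipelineConfig) -> None:
    fx, out = Path(cfg.fixtures_dir), Path(cfg.out_dir)
    labels = read_tsv(fx / "labels.tsv")["group"]
    rel = read_tsv(out / "species_abundance.tsv")
    bc = stats.bray_curtis(rel)
    write_tsv(out / "bray_curtis.tsv", bc, stage="stats")
    ord_res = stats.pcoa(bc, n_axes=2)
    coords = ord_res.coordinates.copy()
    write_tsv(out / "pcoa.tsv", coords, stage="stats")
    perm = stats.permanova(bc, labels, n_perm=cfg.n_perm, rng_seed=cfg.seed)
    write_tsv(
        out / "permanova.tsv",
        pd.DataFrame(
            [{"factor": "group", "pseudo_F": perm.pseudo_f, "R2": perm.r2,
              "p_perm": perm.p_perm, "n_perm": perm.n_perm}]
        ).set_index("factor"),
        stage="stats", params={"n_perm": cfg.n_perm, "seed": cfg.seed},
    )
    diff_sp = stats.differential_features(rel, labels, alpha=cfg.alpha,
                                          use_q=False, case=cfg.case_label)
    write_tsv(out / "differential_species.tsv", diff_sp, stage="stats",
              params={"alpha": cfg.alpha, "use_q": False})
    for level in ("ko", "module"):
        path = out / f"{level}_abundance.tsv"
        if not path.exists():
            raise FileNotFoundError(f"stats stage requires output of functions: {path}")
        mat = read_tsv(path)
        diff = stats.differential_features(mat, labels, alpha=cfg.alpha,
                                           use_q=True, case=cfg.case_label)
        write_tsv(out / f"differential_{level}.tsv", diff, stage="stats",
                  params={"alpha": cfg.alpha, "use_q": True})
    ko_mat = read_tsv(out / "ko_abundance.tsv")
    bc_ko = stats.bray_curtis(ko_mat)
    mant = stats.mantel(bc, bc_ko, n_perm=cfg.n_perm, rng_seed=cfg.seed)
    write_tsv(
        out / "mantel.tsv",
        pd.DataFrame([{"pair": "species_vs_ko", "r": mant.r, "p_perm": mant.p_perm,
                       "n_perm": mant.n_perm}]).set_index("pair"),
        stage="stats",
    )


def stage_classify(cfg: PipelineConfig) -> None:
    fx, out = Path(cfg.fixtures_dir), Path(cfg.out_dir)
    labels = read_tsv(fx / "labels.tsv")["group"]
    for level, fname in (("species", "species_abundance.tsv"), ("ko", "ko_abundance.tsv")):
        mat = read_tsv(out / fname)
        report = classify.classify_report(mat, labels, n_trees=cfg.n_trees,
                                          rng_seed=cfg.seed, case=cfg.case_label)
        summary = pd.DataFrame(
            [{"profile": level, "auc": report.auc, "ci_low": report.ci_low,
              "ci_high": report.ci_high, "n_trees": cfg.n_trees}]
        ).set_index("profile")
        write_tsv(out / f"classifier_{level}.tsv", summary, stage="classify",
                  params={"n_trees": cfg.n_trees, "seed": cfg.seed})
        write_tsv(out / f"classifier_{level}_scores.tsv",
                  report.scores.to_frame(), stage="classify")
        write_tsv(out / f"classifier_{level}_roc.tsv", report.roc_points,
                  stage="classify", index=False)
        write_tsv(out / f"classifier_{level}_top_features.tsv", report.top_features,
                  stage="classify")


_STAGE_FUNCS = {
    "refine": stage_refine,
    "derep": stage_derep,
    "profile": stage_profile,
    "functions": stage_functions,
    "stats": stage_stats,
    "classify": stage_classify,
}


def _stage_io(cfg: PipelineConfig) -> dict[str, tuple[list[Path], list[Path]]]:
    fx, out = Path(cfg.fixtures_dir), Path(cfg.out_dir)
    return {
        "refine": (
            [fx / "quality.tsv", fx / "taxonomy.tsv", fx / "bin_reads.tsv"],
            [out / "refined_manifest.tsv", out / "refine_audit.tsv"],
        ),
        "derep": ([out / "refined_manifest.tsv"], [out / "clusters.tsv"]),
        "profile": (
            [out / "clusters.tsv", fx / "counts.tsv", fx / "species.tsv",
             fx / "labels.tsv"],
            [out / "species_abundance.tsv", out / "diversity.tsv",
             out / "rarefaction.tsv"],
        ),
        "functions": (
            [out / "species_abundance.tsv", fx / "genes.tsv", fx / "hits.tsv",
             fx / "ko_map.tsv"],
            [out / "ko_abundance.tsv", out / "module_abundance.tsv",
             out / "module_species_contribution.tsv"],
        ),
        "stats": (
            [out / "species_abundance.tsv", out / "ko_abundance.tsv",
             out / "module_abundance.tsv", fx / "labels.tsv"],
            [out / "permanova.tsv", out / "differential_species.tsv",
             out / "differential_ko.tsv", out / "differential_module.tsv",
             out / "mantel.tsv", out / "pcoa.tsv", out / "bray_curtis.tsv"],
        ),
        "classify": (
            [out / "species_abundance.tsv", out / "ko_abundance.tsv",
             fx / "labels.tsv"],
            [out / "classifier_species.tsv", out / "classifier_ko.tsv"],
        ),
    }


def _fresh(inputs: list[Path], outputs: list[Path]) -> bool:
    if not outputs or not all(p.exists() for p in outputs):
        return False
    newest_in = max((p.stat().st_mtime for p in inputs if p.exists()), default=0.0)
    oldest_out = min(p.stat().st_mtime for p in outputs)
    return oldest_out >= newest_in


def run_pipeline(cfg: PipelineConfig, force: bool = False,
                 stages: list[str] | None = None) -> dict:
    """Run the chain in dependency order, skipping up-to-date stages.

    Returns (and writes to ``out_dir/manifest.json``) a run manifest with
    per-stage input digests, parameter hash and whether the stage ran.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_map = _stage_io(cfg)
    wanted = stages or list(_STAGE_FUNCS)
    unknown = set(wanted) - set(_STAGE_FUNCS)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    cfg_params = dataclasses.asdict(cfg)
    manifest: dict = {"config": cfg_params, "params_hash": params_hash(cfg_params),
                      "stages": {}}
    for name in _STAGE_FUNCS:
        if name not in wanted:
            continue
        inputs, outputs = io_map[name]
        missing = [str(p) for p in inputs if not p.exists()]
        if missing:
            raise FileNotFoundError(
                f"stage '{name}' is missing upstream inputs: {missing}"
            )
        skipped = not force and _fresh(inputs, outputs)
        t0 = time.perf_counter()
        if not skipped:
            logger.info("running stage %s", name)
            _STAGE_FUNCS[name](cfg)
        manifest["stages"][name] = {
            "skipped": skipped,
            "seconds": round(time.perf_counter() - t0, 3),
            "inputs": {str(p): file_digest(p) for p in inputs},
            "outputs": [str(p) for p in outputs],
            "seed": cfg.seed,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
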