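"""Functional (KO / module / pathway) abundance profiling.

Genes are assigned a KEGG orthologue (KO) by best-hit filtering (e-value
< 1e-10 and alignment coverage > 50% of the protein length; among surviving
hits, the minimal e-value wins). Gene abundance is propagated from the
species' relative abundance times the gene's copy number in the species
representative, and a functional category's abundance is the sum of its
genes' abundances. Categories may overlap (KEGG pathways share KOs), so
category matrices are deliberately not renormalised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix

E_VALUE_MAX = 1e-10
COVERAGE_MIN = 0.5


@dataclass(frozen=True)
class GeneHit:
    """One protein-vs-database hit (BlastKOALA-style)."""

    gene_id: str
    ko: str
    e_value: float
    coverage: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0,1]")


def assign_ko(
    hits_for_gene: Sequence[GeneHit] | pd.DataFrame,
    e_value_max: float = E_VALUE_MAX,
    coverage_min: float = COVERAGE_MIN,
) -> str | None:
    """Best-hit KO for one gene, or None when no hit passes the filter.

    Hits with e-value >= ``e_value_max`` or coverage <= ``coverage_min`` are
    discarded; among survivors the minimal e-value wins, ties broken by
    higher coverage then lexicographic KO.
    """
    if isinstance(hits_for_gene, pd.DataFrame):
        hits = [
            GeneHit(str(r.gene_id) if hasattr(r, "gene_id") else "", r.ko, r.e_value, r.coverage)
            for r in hits_for_gene.itertuples()
        ]
    else:
        hits = list(hits_for_gene)
    survivors = [h for h in hits if h.e_value < e_value_max and h.coverage > coverage_min]
    if not survivors:
        return None
    best = min(survivors, key=lambda h: (h.e_value, -h.coverage, h.ko))
    return best.ko


def assign_kos(
    hits: pd.DataFrame,
    e_value_max: float = E_VALUE_MAX,
    coverage_min: float = COVERAGE_MIN,
) -> pd.Series:
    """Vectorised best-hit KO assignment over a hit table.

    ``hits`` columns: gene_id, ko, e_value, coverage. Returns a Series
    mapping each gene_id with at least one surviving hit to its KO; genes
    whose hits all fail the filter are absent (unassigned).
    """
    ok = hits[(hits["e_value"] < e_value_max) & (hits["coverage"] > coverage_min)]
    if ok.empty:
        return pd.Series(dtype=object, name="ko")
    ranked = ok.sort_values(
        ["gene_id", "e_value", "coverage", "ko"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates("gene_id", keep="first")
    return best.set_index("gene_id")["ko"].rename("ko")


def gene_abundance(
    species_matrix: AbundanceMatrix, gene_catalog: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample gene abundance: species abundance x copy number.

    ``gene_catalog`` columns: gene_id, species_id and optionally copy
    (default 1). Every gene's species must appear in the matrix.
    """
    cat = gene_catalog.copy()
    if "copy" not in cat.columns:
        cat["copy"] = 1
    orphans = cat.loc[~cat["species_id"].isin(species_matrix.feature_ids), "gene_id"]
    if len(orphans):
        raise KeyError(f"genes with unknown species: {list(orphans)[:10]}")
    sp_abund = species_matrix.data[cat["species_id"].to_numpy()].to_numpy()
    out = sp_abund * cat["copy"].to_numpy(dtype=float)
    return pd.DataFrame(out, index=species_matrix.data.index, columns=cat["gene_id"].to_numpy())


def ko_categories(kos: Sequence[str]) -> pd.DataFrame:
    """Degenerate category table where each KO is its own category."""
    return pd.DataFrame({"category_id": list(kos), "ko": list(kos), "level": "ko"})


def category_abundance(
    gene_abundances: pd.DataFrame,
    ko_assignments: pd.Series,
    categories: pd.DataFrame,
    level: str = "module",
) -> AbundanceMatrix:
    """Sum gene abundances into functional categories.

    ``categories`` columns: category_id, ko. A KO shared by overlapping
    categories is counted in each of them; rows therefore need not sum to 1
    and the matrix is tagged non-relative. Categories with no assigned gene
    are emitted as all-zero rows with a warning.
    """
    genes = gene_abundances.columns[gene_abundances.columns.isin(ko_assignments.index)]
    ko_of_gene = ko_assignments.loc[genes]
    cat_ids = list(dict.fromkeys(categories["category_id"]))
    out = pd.DataFrame(0.0, index=gene_abundances.index, columns=cat_ids)
    members = categories.groupby("category_id", sort=False)["ko"].apply(set)
    for cat in cat_ids:
        in_cat = genes[ko_of_gene.isin(members[cat]).to_numpy()]
        if len(in_cat) == 0:
            warnings.warn(f"category {cat!r} has no assigned genes", stacklevel=2)
            continue
        out[cat] = gene_abundances[in_cat].sum(axis=1)
    return AbundanceMatrix(out, level=level, relative=False)


@dataclass
class ContributionResult:
    """Per-species share of one category's abundance, per sample."""

    per_sample: pd.DataFrame       # species x samples, shares in [0,1]
    mean: pd.Series                # per-species mean share across samples
    zero_samples: list[str]        # samples where the category is absent


def species_contribution(
    category_kos: set[str] | Sequence[str],
    gene_abundances: pd.DataFrame,
    ko_assignments: pd.Series,
    species_of_gene: Mapping[str, str],
    species_subset: Sequence[str] | None = None,
) -> ContributionResult:
    """Decompose a category's abundance into per-species shares.

    Per sample, a species' contribution is the summed abundance of its genes
    assigned to the category divided by the category total, so unrestricted
    contributions sum to 1 wherever the category is present. With
    ``species_subset``, only those rows are reported (columns may then sum to
    less than 1). Samples with zero category abundance get zero contributions
    and are listed in ``zero_samples``.
    """
    category_kos = set(category_kos)
    genes = [
        g
        for g in gene_abundances.columns
        if g in ko_assignments.index and ko_assignments[g] in category_kos
    ]
    total = gene_abundances[genes].sum(axis=1) if genes else pd.Series(
        0.0, index=gene_abundances.index
    )
    if not (total > 0).any():
        raise ValueError("category has zero abundance in every sample")
    species = pd.Index(sorted({species_of_gene[g] for g in genes}))
    shares = pd.DataFrame(0.0, index=species, columns=gene_abundances.index)
    safe_total = total.replace(0.0, np.nan)
    for sp in species:
        sp_genes = [g for g in genes if species_of_gene[g] == sp]
        shares.loc[sp] = (gene_abundances[sp_genes].sum(axis=1) / safe_total).fillna(0.0)
    zero_samples = list(total.index[total == 0])
    if species_subset is not None:
        shares = shares.reindex(pd.Index(species_subset).intersection(shares.index))
    return ContributionResult(shares, shares.mean(axis=1), zero_samples)
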