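"""Relative-abundance matrices, taxon roll-ups, diversity and rarefaction.

Species abundance is depth-normalised: per sample, each species' mean
coverage on its representative genome (total mapped reads x read length /
genome length) is divided by the sample's summed coverage. Depth rather than
raw read counts removes genome-length bias. Higher-rank taxon profiles are
obtained by summing the relative abundances of member species, which
conserves row mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class AbundanceMatrix:
    """Samples x features abundance table.

    ``relative`` rows sum to 1 (checked on construction); non-relative
    matrices (e.g. functional-category sums over overlapping categories) may
    not.
    """

    data: pd.DataFrame  # index: sample_ids, columns: feature_ids
    level: str = "species"
    relative: bool = True

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature ids")
        if (self.data.values < 0).any():
            raise ValueError("negative abundances")
        if self.relative:
            sums = self.data.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.index[~np.isclose(sums, 1.0, atol=1e-9)]
                raise ValueError(f"relative rows do not sum to 1: {list(bad)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)


def depth_table(
    counts: pd.DataFrame, read_length: float, genome_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Per-sample, per-species mean coverage from mapped-read counts."""
    missing = [s for s in counts.columns if s not in genome_lengths]
    if missing:
        raise KeyError(f"species without genome lengths: {missing[:5]}")
    lengths = np.array([genome_lengths[s] for s in counts.columns], dtype=float)
    depths = counts.to_numpy(dtype=float) * read_length / lengths
    return pd.DataFrame(depths, index=counts.index, columns=counts.columns)


def relative_abundance(depths: pd.DataFrame) -> AbundanceMatrix:
    """Normalise per-sample depths to relative abundances (rows sum to 1)."""
    if (depths.values < 0).any():
        raise ValueError("negative depths")
    sums = depths.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    rel = depths.div(sums, axis=0)
    return AbundanceMatrix(rel, level="species", relative=True)


def _rank_name(lineage: str, rank: str) -> str:
    idx = RANKS.index(rank)
    parts = lineage.split(";")
    if len(parts) != 7:
        raise ValueError(f"lineage must have 7 ranks: {lineage!r}")
    return parts[idx].strip()


def rollup_taxa(
    matrix: AbundanceMatrix, lineages: Mapping[str, str], rank: str
) -> AbundanceMatrix:
    """Sum member-species abundances into taxa at the requested rank.

    Every species must carry a 7-rank lineage; species with an empty name at
    the rank are pooled under the bare rank prefix (e.g. ``p__``), so row
    sums are preserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    missing = [s for s in matrix.feature_ids if s not in lineages]
    if missing:
        raise KeyError(f"species without lineage: {missing[:5]}")
    taxa = [_rank_name(lineages[s], rank) for s in matrix.feature_ids]
    rolled = matrix.data.T.groupby(pd.Index(taxa, name=rank), sort=True).sum().T
    return AbundanceMatrix(rolled, level=rank, relative=matrix.relative)


def diversity_index(row: Sequence[float] | pd.Series, index: str = "shannon") -> float:
    """Alpha diversity of one relative-abundance row.

    shannon = -sum p ln p over p > 0 (richness and evenness); simpson =
    1 - sum p^2 (probability two random draws differ).
    """
    p = np.asarray(row, dtype=float)
    if p.min() < 0:
        raise ValueError("negative abundances")
    if index == "shannon":
        pos = p[p > 0]
        return float(-(pos * np.log(pos)).sum())
    if index == "simpson":
        return float(1.0 - (p**2).sum())
    raise ValueError(f"unknown diversity index {index!r}")


def rarefaction_curve(
    matrix: AbundanceMatrix,
    group_labels: pd.Series,
    n_reps: int = 30,
    rng_seed: int = 0,
    detection_floor: float = 0.0,
) -> pd.DataFrame:
    """Observed-species accumulation per group by random sample subsets.

    For each group and each subset size m = 1..group size, draws ``n_reps``
    random m-sample subsets without replacement and counts features with
    abundance > ``detection_floor`` in at least one drawn sample; reports the
    median and quartiles over replicates. Columns: group, n_samples, median,
    q1, q3.
    """
    rng = np.random.default_rng(rng_seed)
    present = (matrix.data.to_numpy() > detection_floor)
    rows = []
    for group in pd.unique(group_labels):
        idx = np.flatnonzero((group_labels.reindex(matrix.sample_ids) == group).to_numpy())
        if idx.size == 0:
            raise ValueError(f"group {group!r} has no samples in the matrix")
        for m in range(1, idx.size + 1):
            richness = np.empty(n_reps)
            for r in range(n_reps):
                chosen = rng.choice(idx, size=m, replace=False)
                richness[r] = present[chosen].any(axis=0).sum()
            q1, med, q3 = np.percentile(richness, [25, 50, 75])
            rows.append((group, m, med, q1, q3))
    return pd.DataFrame(rows, columns=["group", "n_samples", "median", "q1", "q3"])
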