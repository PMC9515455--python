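"""Per-sample bin refinement: depth, GC, merging, quality scoring, filtering.

A "bin" is a set of contigs treated as one putative genome. Refinement
follows the standard MAG bookkeeping chain: mean sequencing depth from mapped
reads, G+C content, merging of same-sample bins that look like fragments of
one genome (approximately equal depth and GC, identical species assignment),
the quality score QS = completeness - 5 * contamination, MIMAG quality tiers,
and size/quality filtering with an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqs import gc_fraction

SPECIES_RANK = 6  # index of s__ in a 7-rank lineage string

TIER_HIGH = "high"
TIER_MEDIUM = "medium"
TIER_LOW = "low"
TIER_FAIL = "fail"


@dataclass(frozen=True)
class QualityRecord:
    """CheckM-style completeness/contamination with derived QS and MIMAG tier."""

    completeness: float  # percent, [0, 100]
    contamination: float  # percent, >= 0
    merged: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"completeness out of [0,100]: {self.completeness}")
        if self.contamination < 0:
            raise ValueError(f"contamination must be >= 0: {self.contamination}")

    @property
    def qs(self) -> float:
        return quality_score(self.completeness, self.contamination)

    @property
    def tier(self) -> str:
        return mimag_tier(self.completeness, self.contamination)


@dataclass
class Bin:
    """A contig set with its per-sample depth, GC, lineage and quality."""

    bin_id: str
    sample_id: str
    contigs: list[str]
    depth: float
    lineage: str = "d__;p__;c__;o__;f__;g__;s__"
    quality: QualityRecord | None = None
    merged_from: list[str] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def gc(self) -> float:
        return compute_gc(self.contigs)

    @property
    def species_name(self) -> str:
        """Name at the species rank, '' when unassigned."""
        ranks = self.lineage.split(";")
        if len(ranks) != 7:
            return ""
        return ranks[SPECIES_RANK].removeprefix("s__").strip()


def compute_depth(
    total_mapped_reads: int, average_read_length: float, total_bin_length: int
) -> float:
    """Mean coverage: total_mapped_reads * average_read_length / bin_length."""
    if total_bin_length <= 0:
        raise ValueError("total_bin_length must be > 0")
    if average_read_length <= 0:
        raise ValueError("average_read_length must be > 0")
    if total_mapped_reads < 0:
        raise ValueError("total_mapped_reads must be >= 0")
    return total_mapped_reads * average_read_length / total_bin_length


def compute_gc(contigs: str | list[str]) -> float:
    """GC fraction over contigs, ambiguous bases excluded from the denominator."""
    return gc_fraction(contigs)


def quality_score(completeness: float, contamination: float) -> float:
    """QS = completeness - 5 * contamination."""
    return completeness - 5.0 * contamination


def mimag_tier(completeness: float, contamination: float, qs_min: float = 60.0) -> str:
    """MIMAG draft-genome tier.

    high: completeness >= 90 and contamination < 5; medium: completeness >= 70,
    contamination < 5 and QS >= ``qs_min``; low: completeness >= 50; else fail.
    """
    qs = quality_score(completeness, contamination)
    if completeness >= 90 and contamination < 5:
        return TIER_HIGH
    if completeness >= 70 and contamination < 5 and qs >= qs_min:
        return TIER_MEDIUM
    if completeness >= 50:
        return TIER_LOW
    return TIER_FAIL


def _depth_compatible(d1: float, d2: float, depth_tol: float) -> bool:
    mean = 0.5 * (d1 + d2)
    if mean == 0:
        return d1 == d2
    return abs(d1 - d2) / mean <= depth_tol


def merge_bins(
    bins: list[Bin], depth_tol: float = 0.10, gc_tol: float = 0.02
) -> list[Bin]:
    """Merge same-sample bins that plausibly fragment one genome.

    Two bins are merge-compatible iff their depths differ by at most
    ``depth_tol`` relative to the pair mean, their GC differs by at most
    ``gc_tol``, and their species-rank lineage names are identical and
    non-empty. Compatibility is closed transitively (single linkage), which
    makes the partition independent of input order. Merged bins pool their
    contigs; depth, GC and quality are recombined length-weighted and the
    quality record is flagged ``merged``.
    """
    if not bins:
        return []
    samples = {b.sample_id for b in bins}
    if len(samples) > 1:
        raise ValueError(f"merge_bins expects one sample, got {sorted(samples)}")

    order = sorted(range(len(bins)), key=lambda i: bins[i].bin_id)
    parent = list(range(len(bins)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    gcs = [b.gc for b in bins]
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1 :]:
            bi, bj = bins[i], bins[j]
            name_i = bi.species_name
            if not name_i or name_i != bj.species_name:
                continue
            if not _depth_compatible(bi.depth, bj.depth, depth_tol):
                continue
            if abs(gcs[i] - gcs[j]) > gc_tol:
                continue
            parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in order:
        groups.setdefault(find(i), []).append(i)

    merged: list[Bin] = []
    for members in sorted(groups.values(), key=lambda m: bins[m[0]].bin_id):
        if len(members) == 1:
            merged.append(bins[members[0]])
            continue
        parts = [bins[i] for i in members]
        lengths = np.array([p.total_length for p in parts], dtype=float)
        w = lengths / lengths.sum()
        depth = float(np.dot(w, [p.depth for p in parts]))
        quality = None
        if all(p.quality is not None for p in parts):
            quality = QualityRecord(
                completeness=min(100.0, float(np.dot(w, [p.quality.completeness for p in parts]))),
                contamination=float(np.dot(w, [p.quality.contamination for p in parts])),
                merged=True,
            )
        ids = [p.bin_id for p in parts]
        merged.append(
            Bin(
                bin_id=f"{parts[0].bin_id}+{len(parts) - 1}",
                sample_id=parts[0].sample_id,
                contigs=[c for p in parts for c in p.contigs],
                depth=depth,
                lineage=parts[0].lineage,
                quality=quality,
                merged_from=ids,
            )
        )
    return merged


@dataclass
class FilterResult:
    """Outcome of bin filtering with a per-bin audit of rejection reasons."""

    retained: list[Bin]
    derep_eligible: list[Bin]
    audit: pd.DataFrame  # bin_id, retained, eligible, reasons


def filter_bins(
    bins: list[Bin], min_total_size: int = 200_000, qs_min: float = 60.0
) -> FilterResult:
    """Apply the size filter and dereplication-eligibility rules.

    Bins whose total size is <= ``min_total_size`` bp are dropped outright.
    Of the retained bins, only high/medium MIMAG tiers with QS >= ``qs_min``
    are eligible for species-level dereplication; lower tiers stay in the
    catalogue but never become species representatives.
    """
    retained: list[Bin] = []
    eligible: list[Bin] = []
    rows = []
    for b in bins:
        reasons: list[str] = []
        keep = b.total_length > min_total_size
        if not keep:
            reasons.append("size")
        ok_derep = False
        if keep:
            if b.quality is None:
                reasons.append("no-quality")
            else:
                tier = mimag_tier(b.quality.completeness, b.quality.contamination, qs_min)
                if tier not in (TIER_HIGH, TIER_MEDIUM):
                    reasons.append(f"tier:{tier}")
                elif b.quality.qs < qs_min:
                    reasons.append("qs")
                else:
                    ok_derep = True
            retained.append(b)
        if ok_derep:
            eligible.append(b)
        rows.append((b.bin_id, keep, ok_derep, ";".join(reasons)))
    audit = pd.DataFrame(rows, columns=["bin_id", "retained", "eligible", "reasons"])
    return FilterResult(retained, eligible, audit)


def refined_manifest(bins: list[Bin]) -> pd.DataFrame:
    """Tabular summary of refined bins (one row per bin)."""
    rows = []
    for b in bins:
        q = b.quality
        rows.append(
            {
                "bin_id": b.bin_id,
                "sample_id": b.sample_id,
                "total_length": b.total_length,
                "gc": round(b.gc, 6),
                "depth": b.depth,
                "completeness": q.completeness if q else np.nan,
                "contamination": q.contamination if q else np.nan,
                "qs": q.qs if q else np.nan,
                "tier": q.tier if q else "",
                "lineage": b.lineage,
                "merged_from": ",".join(b.merged_from),
            }
        )
    return pd.DataFrame(rows)
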