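"""Species-level dereplication of MAGs at an ANI threshold.

ANI (average nucleotide identity) is estimated from bottom-s MinHash sketches
of canonical k-mers via the Mash distance formula. Quality-filtered MAGs are
clustered greedily in descending quality-score (QS) order: a MAG joins the
first cluster whose representative exceeds the ANI threshold with it, else it
founds a new cluster, so each cluster's representative is its highest-QS
member by construction. Genomes sharing >95% ANI are conventionally the same
prokaryotic species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .seqs import encode

logger = logging.getLogger(__name__)

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 5000

_U = np.uint64


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorised splitmix64 finaliser; a cheap well-mixed 64-bit hash."""
    z = x + _U(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U(30))) * _U(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U(27))) * _U(0x94D049BB133111EB)
    return z ^ (z >> _U(31))


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed k-mer integers for every window, plus a validity mask."""
    n = len(codes)
    n_win = n - k + 1
    vals = np.zeros(n_win, dtype=_U)
    for j in range(k):
        vals = (vals << _U(2)) | codes[j : j + n_win].astype(_U)
    invalid = (codes > 3).astype(np.int32)
    if invalid.any():
        bad = np.convolve(invalid, np.ones(k, dtype=np.int32), mode="valid") > 0
        return vals, ~bad
    return vals, np.ones(n_win, dtype=bool)


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch over canonical k-mers of one genome."""

    k: int
    sketch_size: int
    hashes: np.ndarray  # sorted uint64, length <= sketch_size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sketch):
            return NotImplemented
        return (
            self.k == other.k
            and self.sketch_size == other.sketch_size
            and np.array_equal(self.hashes, other.hashes)
        )


def sketch(genome: str, k: int = DEFAULT_K, sketch_size: int = DEFAULT_SKETCH_SIZE) -> Sketch:
    """Bottom-``sketch_size`` MinHash sketch of the genome's canonical k-mers.

    Each window is represented by the lexicographically smaller of the k-mer
    and its reverse complement (2-bit packed), hashed with splitmix64; the
    sketch keeps the ``sketch_size`` smallest distinct hash values. Strand
    canonicalisation makes the sketch invariant under reverse complement.
    """
    if len(genome) < k:
        raise ValueError(f"genome length {len(genome)} < k={k}")
    if k < 1 or 2 * k > 64:
        raise ValueError("k must satisfy 1 <= k <= 32")
    codes = encode(genome)
    fwd, fwd_ok = _kmer_codes(codes, k)
    rc_codes = (np.uint8(3) - codes[::-1]) % np.uint8(4)  # ambiguous stay invalid via mask
    rc_codes[codes[::-1] > 3] = 255
    rev, rev_ok = _kmer_codes(rc_codes, k)
    rc_aligned = rev[::-1]  # rc k-mer of window i
    canonical = np.minimum(fwd, rc_aligned)
    valid = fwd_ok & rev_ok[::-1]
    hashes = np.unique(_splitmix64(canonical[valid]))
    if hashes.size == 0:
        raise ValueError("no valid k-mers in genome")
    return Sketch(k=k, sketch_size=sketch_size, hashes=hashes[:sketch_size])


def jaccard(a: Sketch, b: Sketch) -> float:
    """Mash-style Jaccard estimate from two bottom-s sketches.

    Computed on the bottom-s of the union of the two sketches, counting how
    many of those hashes occur in both.
    """
    if a.k != b.k or a.sketch_size != b.sketch_size:
        raise ValueError("sketches have mismatched k or sketch_size")
    if a.hashes.size == 0 or b.hashes.size == 0:
        raise ValueError("empty sketch")
    union = np.union1d(a.hashes, b.hashes)[: a.sketch_size]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    # count shared hashes that fall inside the union's bottom-s
    n_shared = int((shared <= union[-1]).sum()) if shared.size else 0
    return n_shared / union.size


def estimate_ani(a: Sketch, b: Sketch, k: int | None = None) -> float:
    """ANI %% from sketch Jaccard via the Mash distance formula.

    ANI = 100 * (1 + ln(2j/(1+j)) / k), clamped to [0, 100]; identical
    sketches give exactly 100, disjoint sketches give 0.
    """
    k = k if k is not None else a.k
    j = jaccard(a, b)
    if j <= 0.0:
        return 0.0
    if j >= 1.0:
        return 100.0
    ani = 100.0 * (1.0 + math.log(2.0 * j / (1.0 + j)) / k)
    return min(100.0, max(0.0, ani))


@dataclass
class MagRecord:
    """What dereplication needs to know about one quality-filtered MAG."""

    mag_id: str
    sketch: Sketch
    qs: float
    total_length: int
    lineage: str = "d__;p__;c__;o__;f__;g__;s__"


@dataclass
class SpeciesCluster:
    """A set of MAGs sharing >threshold ANI, with its representative."""

    species_id: str
    member_mag_ids: list[str]
    representative_mag_id: str
    lineage: str = "d__;p__;c__;o__;f__;g__;s__"


def select_representative(
    member_ids: Sequence[str], quality: Mapping[str, tuple[float, int]]
) -> str:
    """Highest-QS member; ties broken by larger size, then lexicographic id.

    ``quality`` maps mag_id -> (qs, total_length).
    """
    if not member_ids:
        raise ValueError("empty cluster")
    return min(member_ids, key=lambda m: (-quality[m][0], -quality[m][1], m))


def cluster_species(
    mags: Sequence[MagRecord], ani_threshold: float = 95.0
) -> list[SpeciesCluster]:
    """Greedy QS-ordered single-pass clustering at an ANI threshold.

    MAGs are visited in descending (QS, size) order; each joins the first
    existing cluster whose representative shares ANI > ``ani_threshold`` with
    it, else founds a new cluster. Every MAG ends up in exactly one cluster
    and each representative is its cluster's highest-QS member. The cluster
    lineage is the representative's; member lineages that disagree at the
    species rank are logged as warnings.
    """
    order = sorted(mags, key=lambda m: (-m.qs, -m.total_length, m.mag_id))
    reps: list[MagRecord] = []
    members: list[list[str]] = []
    for mag in order:
        placed = False
        for idx, rep in enumerate(reps):
            if estimate_ani(mag.sketch, rep.sketch) > ani_threshold:
                members[idx].append(mag.mag_id)
                if mag.lineage != rep.lineage:
                    logger.warning(
                        "lineage conflict in cluster %s: %s vs representative %s",
                        rep.mag_id, mag.lineage, rep.lineage,
                    )
                placed = True
                break
        if not placed:
            reps.append(mag)
            members.append([mag.mag_id])
    clusters = []
    for i, (rep, mem) in enumerate(zip(reps, members)):
        clusters.append(
            SpeciesCluster(
                species_id=f"SPC{i:04d}",
                member_mag_ids=mem,
                representative_mag_id=rep.mag_id,
                lineage=rep.lineage,
            )
        )
    return clusters


def ani_matrix(sketches: Mapping[str, Sketch]) -> "pd.DataFrame":
    """Dense pairwise ANI table (small n only; quadratic)."""
    import pandas as pd

    ids = list(sketches)
    out = np.full((len(ids), len(ids)), 100.0)
    for i, a in enumerate(ids):
        for jdx in range(i + 1, len(ids)):
            v = estimate_ani(sketches[a], sketches[ids[jdx]])
            out[i, jdx] = out[jdx, i] = v
    return pd.DataFrame(out, index=ids, columns=ids)
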