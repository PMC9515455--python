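"""Low-level nucleotide-sequence utilities shared across modules.

Sequences are plain Python strings at the API boundary; internally they are
converted to ``uint8`` code arrays (A=0, C=1, G=2, T=3) for vectorised work.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array; non-ACGT bases become 255."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    if codes.size and codes.max() > 3:
        raise ValueError("cannot decode ambiguous (non-ACGT) codes")
    return _DECODE[codes].tobytes().decode()


def gc_fraction(seqs: str | Iterable[str]) -> float:
    """(G+C)/(A+C+G+T) over one or many sequences, ignoring ambiguous bases."""
    if isinstance(seqs, str):
        seqs = [seqs]
    gc = 0
    acgt = 0
    for seq in seqs:
        codes = encode(seq)
        valid = codes <= 3
        acgt += int(valid.sum())
        gc += int(((codes == 1) | (codes == 2)).sum())
    if acgt == 0:
        raise ValueError("no unambiguous bases in input")
    return gc / acgt


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
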