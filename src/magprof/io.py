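"""Tab-separated I/O with provenance header comments.

Every table the pipeline writes starts with ``#`` comment lines declaring the
generating stage and a short parameter hash, so downstream files are
self-describing; readers skip comments.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd


def params_hash(params: dict[str, Any]) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(
    path: str | Path,
    frame: pd.DataFrame,
    stage: str = "",
    params: dict[str, Any] | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if stage:
            fh.write(f"# stage: {stage}\n")
        if params is not None:
            fh.write(f"# params_hash: {params_hash(params)}\n")
        frame.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
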