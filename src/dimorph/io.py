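"""Tabular I/O conventions shared by every pipeline stage.

Tables are tab-separated with "NA" as the missing marker and values at 12
significant digits (lossless for the pipeline's quantities); matrices are
CSV (see :mod:`dimorph.gmatrix`).  Each writer can stamp a comment header
(``# key: value`` lines) carrying the seed and a configuration hash so
any artifact can be traced to the run that produced it; readers skip
those lines.  Windows and Unix line endings are both accepted on input.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "read_tissue_table",
    "config_hash",
    "file_sha256",
]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", float_format="%.12g", na_rep="NA", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(
            path, sep="\t", comment="#", index_col=index_col, na_values=["NA"],
            float_precision="round_trip",
        )
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed table ({err})") from err


def read_tissue_table(path: str | Path) -> pd.DataFrame:
    """Tissue x gene expression table (rows tissues, columns genes)."""
    df = read_table(path)
    if df.shape[0] < 2:
        raise ValueError(f"{path}: tissue table needs >=2 tissue rows")
    return df
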