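"""Tab-separated and GMT file I/O used across the pipeline.

All tabular interchange files are plain TSV with a header row; lines starting
with ``#`` are metadata (written as ``# key: value``) and are ignored on read.
Gene sets use the GMT convention: one set per line,
``name <tab> description <tab> gene1 <tab> gene2 ...``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_gmt",
    "write_gmt",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, meta: Mapping | None = None,
              index: bool = False) -> None:
    """Write ``df`` as TSV, prepending ``# key: value`` metadata lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (``#`` lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_gmt(gene_sets: Mapping[str, list], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *map(str, genes)]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set name: [genes]}``.

    Duplicate genes within a set are dropped (first occurrence kept);
    malformed lines (fewer than three fields) raise ``ValueError``.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT requires name, description, and at least one gene"
                )
            name, _desc, *genes = fields
            seen: dict[str, None] = {}
            for g in genes:
                if g and g not in seen:
                    seen[g] = None
            sets[name] = list(seen)
    return sets
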