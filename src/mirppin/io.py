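"""Small readers/writers for the tab-separated interchange formats."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .network import canonical_gene

__all__ = ["read_gmt", "write_gmt", "read_probe_map", "read_id_list"]


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set collection: term, description, then member genes."""
    collection: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        term = parts[0]
        collection[term] = {canonical_gene(g) for g in parts[2:] if g}
    return collection


def write_gmt(collection: Mapping[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term in sorted(collection):
            fh.write(f"{term}\t{description}\t" + "\t".join(sorted(collection[term])) + "\n")


def read_probe_map(path) -> dict[str, str]:
    """Two-column probe -> gene-symbol TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map needs two columns: probe, gene")
    return {
        str(p): canonical_gene(g)
        for p, g in df.iloc[:, :2].itertuples(index=False)
        if pd.notna(g)
    }


def read_id_list(path) -> list[str]:
    """One identifier per line (first whitespace-separated token)."""
    out = []
    for line in Path(path).read_text().splitlines():
        tok = line.strip().split()
        if tok:
            out.append(tok[0])
    return out
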