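"""GMT gene-set files and the pipeline's tabular outputs."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .scoring import GeneSet

__all__ = ["read_gmt", "write_gmt", "read_expression_tsv"]


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs >= 3 columns")
            sets.append(GeneSet(fields[0], tuple(g for g in fields[2:] if g)))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for gs in gene_sets:
            desc = descriptions.get(gs.name, "na")
            fh.write("\t".join([gs.name, desc, *gs.genes]) + "\n")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    return df
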