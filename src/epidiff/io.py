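"""Small readers/writers for the plain-text formats used across modules:
GMT gene sets, BED intervals and ranked-list TSVs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_gmt", "write_gmt", "read_bed", "write_bed", "read_ranked_list"]


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line with fewer than 3 fields")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_bed(path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    """BED-like TSV without header; extra columns beyond `names` ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, : len(names)]
    df.columns = list(names)[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, columns=("chrom", "start", "end")) -> None:
    df[list(columns)].to_csv(path, sep="\t", header=False, index=False)


def read_ranked_list(path) -> pd.DataFrame:
    """Ranked differential table: gene, p, lfc (TSV with header)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "p", "lfc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[["gene", "p", "lfc"]]
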