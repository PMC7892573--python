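"""Rank-rank hypergeometric overlap of two signed gene rankings.

Each table ranks genes by the signed metric -log10(p) x sign(log2 fold
change). The two rankings are stratified at the metric's sign into four
quadrants (up-up, down-down and the two discordant pairings); within each
quadrant, overlaps of the top-i genes of one list with the top-j of the
other are tested with an upper-tail hypergeometric at a fixed rank step,
and the whole grid is adjusted jointly with Benjamini-Yekutieli. The
gene lists at the most significant concordant cells are the output of
interest for downstream enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import P_FLOOR, by_adjust, hypergeom_tail

__all__ = [
    "signed_metric",
    "prepare_table",
    "overlay",
    "correct_by",
    "quadrant_genes",
    "RankRankOverlap",
    "RRHOResults",
]

QUADRANTS = ("uu", "dd", "ud", "du")  # (A-direction, B-direction)


def signed_metric(p, lfc):
    """-log10(p) x sign(lfc); sign(0) = 0, p floored at 1e-300."""
    p = np.asarray(p, dtype=float)
    lfc = np.asarray(lfc, dtype=float)
    if (p > 1).any() or (p < 0).any():
        raise ValueError("p values outside [0, 1]")
    return -np.log10(np.maximum(p, P_FLOOR)) * np.sign(lfc)


def prepare_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add the signed metric and a deterministic descending rank.

    Expects gene, p, lfc columns; one row per gene. Metric ties are broken
    by gene id so reruns are bit-identical.
    """
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene ids")
    out = df.copy()
    out["metric"] = signed_metric(out["p"], out["lfc"])
    out = out.sort_values(
        ["metric", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out


def _directional_order(table: pd.DataFrame, direction: str) -> np.ndarray:
    """Gene ids most-extreme-first for one direction of one table."""
    if direction == "u":
        sub = table[table["metric"] > 0]
        return sub["gene"].to_numpy()  # already descending
    sub = table[table["metric"] < 0]
    return sub["gene"].to_numpy()[::-1]  # most negative first


def overlay(table_a: pd.DataFrame, table_b: pd.DataFrame, step: int = 140) -> pd.DataFrame:
    """The four-quadrant overlap grid at rank step `step`.

    Tables are restricted to their shared gene universe (disjoint universes
    raise ValueError). If the universe holds fewer than 2 x `step` genes
    the step shrinks to ~N/10 so small inputs still produce a grid. Each
    cell tests the overlap of the top-i genes of A (in its quadrant
    direction) with the top-j of B against a hypergeometric draw from the
    N shared genes. Returns one row per cell: quadrant, i, j, overlap, p,
    neg_log10_p.
    """
    shared = sorted(set(table_a["gene"]) & set(table_b["gene"]))
    if not shared:
        raise ValueError("gene universes are disjoint")
    ta = prepare_table(table_a[table_a["gene"].isin(shared)])
    tb = prepare_table(table_b[table_b["gene"].isin(shared)])
    n = len(shared)
    if n < 2 * step:
        step = max(1, n // 10)

    rows = []
    for qa, qb in QUADRANTS:
        genes_a = _directional_order(ta, qa)
        genes_b = _directional_order(tb, qb)
        if genes_a.size == 0 or genes_b.size == 0:
            continue
        pos_b = {g: r for r, g in enumerate(genes_b)}
        # rank in B's directional list of each of A's genes (inf if absent)
        rb = np.array([pos_b.get(g, np.inf) for g in genes_a])
        ii = np.arange(step, genes_a.size + 1, step)
        jj = np.arange(step, genes_b.size + 1, step)
        if ii.size == 0:
            ii = np.array([genes_a.size])
        if jj.size == 0:
            jj = np.array([genes_b.size])
        for i in ii:
            sub = np.sort(rb[:i])
            for j in jj:
                k = int(np.searchsorted(sub, j, side="left"))
                p = float(hypergeom_tail(k, n, int(j), int(i)))
                rows.append((qa + qb, int(i), int(j), k, p, -np.log10(max(p, P_FLOOR))))
    grid = pd.DataFrame(
        rows, columns=["quadrant", "i", "j", "overlap", "p", "neg_log10_p"]
    )
    grid.attrs["step"] = step
    grid.attrs["n_genes"] = n
    return grid


def correct_by(grid: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Yekutieli adjustment jointly over all grid cells."""
    out = grid.copy()
    out["p_adj"] = by_adjust(out["p"].to_numpy())
    out["neg_log10_p_adj"] = -np.log10(np.maximum(out["p_adj"], P_FLOOR))
    out.attrs.update(grid.attrs)
    return out


def quadrant_genes(
    grid: pd.DataFrame, table_a: pd.DataFrame, table_b: pd.DataFrame
) -> dict[str, list[str]]:
    """Overlapping genes at each concordant quadrant's best cell.

    The best cell maximises the BY-adjusted significance (ties resolved by
    the smaller (i, j)); an empty quadrant yields an empty list.
    """
    if "p_adj" not in grid.columns:
        raise ValueError("grid must be BY-corrected first (correct_by)")
    shared = sorted(set(table_a["gene"]) & set(table_b["gene"]))
    ta = prepare_table(table_a[table_a["gene"].isin(shared)])
    tb = prepare_table(table_b[table_b["gene"].isin(shared)])
    out: dict[str, list[str]] = {}
    for quad in ("uu", "dd"):
        sub = grid[grid["quadrant"] == quad]
        if sub.empty:
            out[quad] = []
            continue
        best = sub.sort_values(["p_adj", "i", "j"], kind="stable").iloc[0]
        ga = _directional_order(ta, quad[0])[: int(best["i"])]
        gb = _directional_order(tb, quad[1])[: int(best["j"])]
        out[quad] = sorted(set(ga) & set(gb))
    return out


def grid_matrix(grid: pd.DataFrame, quadrant: str, value: str = "neg_log10_p_adj") -> pd.DataFrame:
    """One quadrant of the grid as an i x j matrix (for dumping/plotting)."""
    sub = grid[grid["quadrant"] == quadrant]
    return sub.pivot(index="i", columns="j", values=value)


# ---------------------------------------------------------------------------
# model facade


@dataclass
class RRHOResults:
    """Corrected overlap grid plus the inputs it came from."""

    grid: pd.DataFrame
    table_a: pd.DataFrame
    table_b: pd.DataFrame
    step: int
    n_genes: int
    params: dict = field(default_factory=dict)

    def quadrant_genes(self) -> dict[str, list[str]]:
        return quadrant_genes(self.grid, self.table_a, self.table_b)

    def max_signal(self) -> pd.Series:
        """Maximum BY-adjusted -log10 p per quadrant."""
        return self.grid.groupby("quadrant")["neg_log10_p_adj"].max()

    def to_matrix(self, quadrant: str, value: str = "neg_log10_p_adj") -> pd.DataFrame:
        return grid_matrix(self.grid, quadrant, value)

    def summary(self) -> str:
        sig = self.max_signal()
        lines = [
            "Rank-rank hypergeometric overlap",
            f"  shared genes: {self.n_genes}",
            f"  step:         {self.step}",
            f"  grid cells:   {len(self.grid)}",
        ]
        for q in QUADRANTS:
            if q in sig.index:
                lines.append(f"  max -log10 adj p [{q}]: {sig[q]:.2f}")
        return "\n".join(lines)


class RankRankOverlap:
    """Rank-rank overlap model over two (gene, p, lfc) tables."""

    def __init__(self, table_a: pd.DataFrame, table_b: pd.DataFrame):
        self.table_a = table_a
        self.table_b = table_b

    def fit(self, step: int = 140) -> RRHOResults:
        grid = correct_by(overlay(self.table_a, self.table_b, step=step))
        return RRHOResults(
            grid,
            self.table_a,
            self.table_b,
            step=grid.attrs["step"],
            n_genes=grid.attrs["n_genes"],
            params={"step_requested": step},
        )
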