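"""Region-based gene-set enrichment with regulatory-domain association.

Genes get a basal regulatory domain (5 kb upstream to 1 kb downstream of
the TSS, strand-aware) extended on each side up to the nearest neighbouring
basal domain or at most 1 Mb. A query region hits a gene if its midpoint
lies in the gene's extended domain. Each term is tested two ways: an
upper-tail binomial on the number of regions landing in the term's domain
union (against the union's genome fraction), and an upper-tail
hypergeometric on the genes hit. Terms pass only if both tests clear fold
>= 1.5 and BH FDR q <= 0.1 and at least five term genes are hit; a
co-occurrence score sums -log10 binomial p over the transition types in
which a term passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import P_FLOOR, bh_adjust, binom_tail, hypergeom_tail

__all__ = [
    "basal_plus_extension",
    "associate_regions",
    "binomial_enrichment",
    "hypergeom_enrichment",
    "filter_terms",
    "co_occurrence",
    "group_by_category",
    "RegionEnrichment",
    "EnrichmentResults",
]


# ---------------------------------------------------------------------------
# regulatory domains


def basal_plus_extension(
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    basal_up: int = 5_000,
    basal_down: int = 1_000,
    max_ext: int = 1_000_000,
) -> pd.DataFrame:
    """Basal-plus-extension regulatory domains for each gene.

    The basal domain runs `basal_up` bp upstream to `basal_down` bp
    downstream of the TSS, strand-aware. Each side is then extended to the
    nearest basal-domain boundary of another gene, capped at `max_ext` from
    the TSS and clipped to the chromosome; extension never shrinks below
    the gene's own basal domain. Overlapping basal domains are allowed.

    Returns gene_id, chrom, strand, tss, basal_start, basal_end,
    ext_start, ext_end.
    """
    rows = []
    for chrom, g in genes.groupby("chrom", sort=True):
        size = chrom_sizes[chrom]
        tss = g["tss"].to_numpy()
        plus = (g["strand"] == "+").to_numpy()
        b_start = np.where(plus, tss - basal_up, tss - basal_down)
        b_end = np.where(plus, tss + basal_down, tss + basal_up)
        b_start = np.clip(b_start, 0, size)
        b_end = np.clip(b_end, 0, size)
        for i in range(len(g)):
            others = np.arange(len(g)) != i
            left_edges = b_end[others][b_end[others] <= b_start[i]]
            right_edges = b_start[others][b_start[others] >= b_end[i]]
            left = left_edges.max() if left_edges.size else 0
            right = right_edges.min() if right_edges.size else size
            e_start = max(int(left), int(tss[i]) - max_ext, 0)
            e_end = min(int(right), int(tss[i]) + max_ext, size)
            e_start = min(e_start, int(b_start[i]))  # never inside own basal
            e_end = max(e_end, int(b_end[i]))
            rows.append(
                (
                    g["gene_id"].iat[i], chrom, g["strand"].iat[i], int(tss[i]),
                    int(b_start[i]), int(b_end[i]), e_start, e_end,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "strand", "tss",
            "basal_start", "basal_end", "ext_start", "ext_end",
        ],
    )


def associate_regions(regions: pd.DataFrame, domains: pd.DataFrame) -> list[list[str]]:
    """Genes whose extended domain contains each region's midpoint.

    Returns one (possibly empty) gene-id list per region, in region order;
    a midpoint inside several overlapping domains hits every one of them.
    """
    hits: list[list[str]] = []
    by_chrom = {c: g for c, g in domains.groupby("chrom", sort=False)}
    for _, r in regions.iterrows():
        mid = (int(r["start"]) + int(r["end"])) // 2
        g = by_chrom.get(r["chrom"])
        if g is None:
            hits.append([])
            continue
        sel = (g["ext_start"].to_numpy() <= mid) & (mid < g["ext_end"].to_numpy())
        hits.append(list(g["gene_id"].to_numpy()[sel]))
    return hits


def _union_bp(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    ivs = sorted(intervals)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def _term_domain_union(domains: pd.DataFrame, term_genes) -> dict[str, list]:
    sub = domains[domains["gene_id"].isin(set(term_genes))]
    out: dict[str, list] = {}
    for chrom, g in sub.groupby("chrom", sort=False):
        ivs = sorted(zip(g["ext_start"], g["ext_end"]))
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = merged
    return out


# ---------------------------------------------------------------------------
# the two tests


def binomial_enrichment(
    regions: pd.DataFrame,
    term_genes,
    domains: pd.DataFrame,
    genome_bp: int,
):
    """Binomial test of regions falling in the term's domain union.

    p_term is the union's fraction of the background genome; k the number
    of region midpoints inside it. Returns (k_hits, p_term, fold, p_binom);
    a degenerate p_term (0 or 1) returns NaNs (term skipped).
    """
    union = _term_domain_union(domains, term_genes)
    bp = sum(_union_bp([tuple(iv) for iv in ivs]) for ivs in union.values())
    p_term = bp / genome_bp
    n = len(regions)
    if p_term <= 0.0 or p_term >= 1.0:
        return 0, p_term, np.nan, np.nan
    k = 0
    for _, r in regions.iterrows():
        mid = (int(r["start"]) + int(r["end"])) // 2
        for s, e in union.get(r["chrom"], ()):
            if s <= mid < e:
                k += 1
                break
    fold = k / (n * p_term) if n else np.nan
    p = float(binom_tail(k, n, p_term)) if n else np.nan
    return k, p_term, fold, p


def hypergeom_enrichment(genes_hit, term_genes, background_genes):
    """Hypergeometric test on genes hit by any region.

    Draws = genes hit overall; successes = term genes within the
    background. Returns (k_term_hit, fold, p_hyper).
    """
    bg = set(background_genes)
    if not bg:
        raise ValueError("empty background gene universe")
    hit = set(genes_hit) & bg
    term = set(term_genes) & bg
    k = len(hit & term)
    n_pop, n_succ, n_draw = len(bg), len(term), len(hit)
    expected = n_draw * n_succ / n_pop
    fold = k / expected if expected > 0 else np.nan
    p = float(hypergeom_tail(k, n_pop, n_succ, n_draw))
    return k, fold, p


# ---------------------------------------------------------------------------
# filtering, co-occurrence, grouping


def filter_terms(
    rows: pd.DataFrame,
    fc_min: float = 1.5,
    q_max: float = 0.1,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Apply the dual-test pass rule and return rows with q values filled.

    BH adjustment runs within each test family (binomial, hypergeometric)
    separately over the supplied rows. A term passes iff both tests have
    fold >= `fc_min` and q <= `q_max`, and at least `min_genes` of its
    genes are hit.
    """
    out = rows.copy().reset_index(drop=True)
    testable = out["p_binom"].notna() & out["p_hyper"].notna()
    out["q_binom"] = np.nan
    out["q_hyper"] = np.nan
    out.loc[testable, "q_binom"] = bh_adjust(out.loc[testable, "p_binom"])
    out.loc[testable, "q_hyper"] = bh_adjust(out.loc[testable, "p_hyper"])
    out["pass"] = (
        testable
        & (out["fold_binom"] >= fc_min)
        & (out["q_binom"] <= q_max)
        & (out["fold_hyper"] >= fc_min)
        & (out["q_hyper"] <= q_max)
        & (out["genes_hit"] >= min_genes)
    )
    return out


def co_occurrence(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Co-occurrence score across transition-type enrichment tables.

    `tables` maps a transition-type label to a filtered enrichment frame
    (with `term`, `pass`, `p_binom` columns). For each term passing in at
    least one type, the score is the sum over passing types of
    -log10(raw binomial p). Returns term, score, n_types, types —
    descending by score.
    """
    acc: dict[str, dict] = {}
    for typ, df in tables.items():
        for _, r in df[df["pass"]].iterrows():
            e = acc.setdefault(r["term"], {"score": 0.0, "types": []})
            e["score"] += -np.log10(max(float(r["p_binom"]), P_FLOOR))
            e["types"].append(typ)
    rows = [
        (t, e["score"], len(e["types"]), sorted(e["types"]))
        for t, e in acc.items()
    ]
    out = pd.DataFrame(rows, columns=["term", "score", "n_types", "types"])
    return out.sort_values("score", ascending=False).reset_index(drop=True)


def group_by_category(
    terms, keyword_map: dict[str, list[str]], other: str = "other"
) -> pd.DataFrame:
    """Assign terms to categories by first-match substring keywords.

    Matching is case-insensitive in `keyword_map` order; unmatched terms
    fall into `other`. Returns term, category plus per-category counts in
    `.attrs["counts"]`.
    """
    rows = []
    for term in terms:
        low = term.lower()
        cat = other
        for c, kws in keyword_map.items():
            if any(kw.lower() in low for kw in kws):
                cat = c
                break
        rows.append((term, cat))
    out = pd.DataFrame(rows, columns=["term", "category"])
    out.attrs["counts"] = out["category"].value_counts()
    return out


# ---------------------------------------------------------------------------
# model facade


@dataclass
class EnrichmentResults:
    """Per-term dual-test results with the pass flag applied."""

    table: pd.DataFrame
    n_regions: int
    params: dict = field(default_factory=dict)

    @property
    def passing(self) -> pd.DataFrame:
        return self.table[self.table["pass"]].reset_index(drop=True)

    def summary(self) -> str:
        return "\n".join(
            [
                "Region gene-set enrichment",
                f"  regions:        {self.n_regions}",
                f"  terms tested:   {len(self.table)}",
                f"  terms passing:  {int(self.table['pass'].sum())}",
                f"  filters:        fold >= {self.params.get('fc_min')}, "
                f"q <= {self.params.get('q_max')}, "
                f">= {self.params.get('min_genes')} genes hit",
            ]
        )


class RegionEnrichment:
    """GREAT-style enrichment of a region set against flat gene sets.

    Parameters
    ----------
    regions : frame of chrom, start, end query regions.
    gene_sets : mapping of term id -> gene-id list.
    genes : gene model (gene_id, chrom, strand, tss, ...).
    chrom_sizes : chromosome lengths; their sum is the background bp.
    """

    def __init__(
        self,
        regions: pd.DataFrame,
        gene_sets: dict[str, list[str]],
        genes: pd.DataFrame,
        chrom_sizes: dict[str, int],
        basal_up: int = 5_000,
        basal_down: int = 1_000,
        max_ext: int = 1_000_000,
    ):
        self.regions = regions.reset_index(drop=True)
        self.gene_sets = dict(gene_sets)
        self.genes = genes
        self.chrom_sizes = dict(chrom_sizes)
        self.domains = basal_plus_extension(
            genes, chrom_sizes, basal_up, basal_down, max_ext
        )
        self.genome_bp = sum(chrom_sizes.values())

    def fit(
        self, fc_min: float = 1.5, q_max: float = 0.1, min_genes: int = 5
    ) -> EnrichmentResults:
        background = list(self.domains["gene_id"])
        region_hits = associate_regions(self.regions, self.domains)
        genes_hit = sorted({g for gl in region_hits for g in gl})
        rows = []
        for term, members in self.gene_sets.items():
            members = [g for g in members if g in set(background)]
            if not members:
                warnings.warn(f"term {term!r} empty; excluded", stacklevel=2)
                continue
            k, p_term, fold_b, p_b = binomial_enrichment(
                self.regions, members, self.domains, self.genome_bp
            )
            kh, fold_h, p_h = hypergeom_enrichment(genes_hit, members, background)
            rows.append(
                {
                    "term": term,
                    "n_regions": len(self.regions),
                    "k_hits": k,
                    "p_term": p_term,
                    "fold_binom": fold_b,
                    "p_binom": p_b,
                    "genes_hit": kh,
                    "fold_hyper": fold_h,
                    "p_hyper": p_h,
                }
            )
        columns = [
            "term", "n_regions", "k_hits", "p_term", "fold_binom",
            "p_binom", "genes_hit", "fold_hyper", "p_hyper",
        ]
        frame = pd.DataFrame(rows, columns=columns)
        table = filter_terms(frame, fc_min, q_max, min_genes)
        return EnrichmentResults(
            table,
            len(self.regions),
            params={"fc_min": fc_min, "q_max": q_max, "min_genes": min_genes},
        )
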