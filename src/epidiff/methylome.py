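"""Per-cytosine methylation tables: IO, context classification, strand
merging, filtering and genome-wide summaries.

Coordinates are 0-based half-open throughout; 1-based appears only in
formatted output. A site's methylation fraction is n_meth / n_total and is
undefined (NaN), not zero, where a sample has no coverage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CONTEXTS

logger = logging.getLogger(__name__)

__all__ = [
    "MethylTable",
    "read_calls",
    "build_table",
    "classify_contexts",
    "merge_cg",
    "filter_coverage",
    "mask_sites",
    "context_summary",
    "level_histogram",
    "profile_over_intervals",
    "state_methylation",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class MethylTable:
    """Methylated/total counts for many sites across many samples.

    Attributes
    ----------
    sites : DataFrame with columns chrom, pos, strand, context, sorted by
        (chrom, pos). Strand-merged CG rows carry strand ".".
    meth, total : int arrays of shape (n_sites, n_samples).
    samples : sample identifiers, aligned with the count columns.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.meth.shape != self.total.shape:
            raise ValueError("meth/total shape mismatch")
        if (self.meth > self.total).any():
            raise ValueError("n_meth exceeds n_total")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def fraction(self) -> np.ndarray:
        """Per-site per-sample methylation fraction; NaN where uncovered."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / self.total, np.nan)

    def take(self, row_idx) -> "MethylTable":
        row_idx = np.asarray(row_idx)
        return MethylTable(
            self.sites.iloc[row_idx].reset_index(drop=True),
            self.meth[row_idx],
            self.total[row_idx],
            list(self.samples),
        )

    def subset_samples(self, names) -> "MethylTable":
        cols = [self.samples.index(s) for s in names]
        return MethylTable(
            self.sites.copy(), self.meth[:, cols], self.total[:, cols], list(names)
        )

    def select_context(self, context: str) -> "MethylTable":
        """Rows for a context group: "CG" keeps all CGN rows, else exact."""
        ctx = self.sites["context"].astype(str)
        mask = ctx.str.startswith("CG") if context == "CG" else ctx == context
        return self.take(np.flatnonzero(mask.to_numpy()))


# ---------------------------------------------------------------------------
# IO


def read_calls(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read one sample's cytosine methylation calls.

    Dialects
    --------
    ``tsv``
        Seven columns: chrom, start (0-based), end, strand, context,
        n_meth, n_total — the simulator's output format, with header.
    ``bedGraph-cov``
        Bismark-style coverage: chrom, start (1-based), end, percent,
        count_methylated, count_unmethylated; no strand or context (filled
        with "." and NaN).

    Malformed lines raise ValueError naming the line number. An empty file
    returns an empty frame with a warning.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"chrom", "start", "strand", "context", "n_meth", "n_total"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        df = df.rename(columns={"start": "pos"})
        df = df[["chrom", "pos", "strand", "context", "n_meth", "n_total"]]
    elif dialect == "bedGraph-cov":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
            dtype={"chrom": str},
        )
        df["pos"] = df["start"] - 1  # to 0-based
        df["strand"] = "."
        df["context"] = np.nan
        df["n_total"] = df["n_meth"] + df["n_unmeth"]
        df = df[["chrom", "pos", "strand", "context", "n_meth", "n_total"]]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if df.empty:
        warnings.warn(f"{path}: no records", stacklevel=2)
        return df.reset_index(drop=True)
    bad = np.flatnonzero(
        (df["n_meth"] < 0) | (df["n_total"] < 0) | (df["n_meth"] > df["n_total"])
    )
    if bad.size:
        line = int(bad[0]) + 2  # 1-based, after header
        raise ValueError(
            f"{path}: invalid counts at data line {line} "
            f"(n_meth={df['n_meth'].iat[bad[0]]}, n_total={df['n_total'].iat[bad[0]]})"
        )
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def build_table(records_by_sample: dict[str, pd.DataFrame]) -> MethylTable:
    """Align per-sample record frames on (chrom, pos, strand) into one table.

    Sites absent from a sample get zero counts (fraction undefined).
    """
    keys = ["chrom", "pos", "strand"]
    frames = []
    for s, df in records_by_sample.items():
        d = df.set_index(keys)[["context", "n_meth", "n_total"]]
        frames.append(d.rename(columns={"n_meth": f"m_{s}", "n_total": f"t_{s}"}))
    ctx = pd.concat([f[["context"]] for f in frames]).groupby(level=keys).first()
    merged = ctx
    for f in frames:
        merged = merged.join(f.drop(columns="context"), how="outer")
    merged = merged.sort_index().reset_index()
    samples = list(records_by_sample)
    meth = merged[[f"m_{s}" for s in samples]].fillna(0).to_numpy(dtype=np.int64)
    total = merged[[f"t_{s}" for s in samples]].fillna(0).to_numpy(dtype=np.int64)
    sites = merged[["chrom", "pos", "strand", "context"]]
    return MethylTable(sites, meth, total, samples)


# ---------------------------------------------------------------------------
# context classification


def classify_contexts(sequences: dict[str, str], records: pd.DataFrame) -> pd.DataFrame:
    """Fill the CNN context of each record from the reference sequence.

    Plus-strand context is the triplet at pos..pos+2; minus-strand context is
    the reverse complement of the triplet ending at pos, i.e. the triplet
    read 5'->3' on the minus strand. Sites whose triplet is truncated by a
    chromosome end are dropped (context undefined). A record whose reference
    base on its strand is not C raises ValueError.
    """
    out = []
    for chrom, g in records.groupby("chrom", sort=False):
        seq = sequences[chrom].upper()
        n = len(seq)
        pos = g["pos"].to_numpy()
        if (pos < 0).any() or (pos >= n).any():
            raise ValueError(f"{chrom}: position outside sequence")
        strand = g["strand"].to_numpy()
        base = np.array([seq[p] for p in pos])
        want = np.where(strand == "+", "C", "G")
        if (base != want).any():
            i = int(np.flatnonzero(base != want)[0])
            raise ValueError(
                f"{chrom}:{pos[i]}({strand[i]}): reference base is "
                f"{base[i]!r}, not a cytosine on that strand"
            )
        keep = np.where(strand == "+", pos + 2 < n, pos - 2 >= 0)
        g = g[keep].copy()
        pos = pos[keep]
        strand = strand[keep]
        ctx = [
            seq[p: p + 3]
            if s == "+"
            else seq[p - 2: p + 1].translate(_COMPLEMENT)[::-1]
            for p, s in zip(pos, strand)
        ]
        g["context"] = pd.Categorical(ctx, categories=list(CONTEXTS))
        out.append(g)
    return pd.concat(out, ignore_index=True) if out else records.iloc[0:0].copy()


# ---------------------------------------------------------------------------
# strand merging


def merge_cg(table: MethylTable) -> MethylTable:
    """Strand-merge CG dyads; non-CG rows pass through unchanged.

    Counts of the plus-strand C at position i and the minus-strand C at
    i + 1 are summed and assigned to position i with strand ".". Unpaired
    CGs keep the single strand's counts (a lone minus-strand C is assigned
    to its dyad position i = pos - 1). Total counts are conserved.
    """
    ctx = table.sites["context"].astype(str)
    is_cg = ctx.str.startswith("CG").to_numpy()
    cg_rows = np.flatnonzero(is_cg)
    other_rows = np.flatnonzero(~is_cg)

    if cg_rows.size:
        sub = table.sites.iloc[cg_rows]
        dyad = np.where(
            sub["strand"].to_numpy() == "+",
            sub["pos"].to_numpy(),
            sub["pos"].to_numpy() - 1,
        )
        key = pd.MultiIndex.from_arrays([sub["chrom"].to_numpy(), dyad])
        codes, uniques = pd.factorize(key, sort=True)
        n_dyads = len(uniques)
        cg_meth = np.zeros((n_dyads, len(table.samples)), dtype=np.int64)
        cg_total = np.zeros_like(cg_meth)
        np.add.at(cg_meth, codes, table.meth[cg_rows])
        np.add.at(cg_total, codes, table.total[cg_rows])
        cg_sites = pd.DataFrame(
            {
                "chrom": uniques.get_level_values(0),
                "pos": uniques.get_level_values(1),
                "strand": ".",
                "context": "CGN",
            }
        )
    else:
        cg_sites = table.sites.iloc[0:0]
        cg_meth = np.empty((0, len(table.samples)), dtype=table.meth.dtype)
        cg_total = cg_meth.copy()

    sites = pd.concat(
        [cg_sites, table.sites.iloc[other_rows]], ignore_index=True
    )
    meth = np.concatenate([cg_meth, table.meth[other_rows]])
    total = np.concatenate([cg_total, table.total[other_rows]])
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    sites["context"] = sites["context"].astype(str)
    return MethylTable(sites, meth[order], total[order], list(table.samples))


# ---------------------------------------------------------------------------
# filtering


def filter_coverage(
    table: MethylTable,
    meta: pd.DataFrame | None = None,
    min_cov: int = 4,
    min_samples_per_group: int | None = 10,
) -> MethylTable:
    """Coverage filter for differential or characterisation analyses.

    With `min_samples_per_group` set (the differential preset, defaults
    4/10), a site is retained iff at least that many samples have coverage
    >= `min_cov` in *each* group of `meta`. With `min_samples_per_group`
    None (the characterisation preset, typically min_cov=5), a site is
    retained iff its cohort-wide mean coverage is >= `min_cov`.
    """
    if min_samples_per_group is None:
        keep = table.total.mean(axis=1) >= min_cov
        return table.take(np.flatnonzero(keep))
    if meta is None:
        raise ValueError("meta required for the per-group coverage filter")
    ok = np.ones(table.n_sites, dtype=bool)
    groups = meta["group"].unique()
    if len(groups) < 2:
        raise ValueError("two groups required")
    for grp in groups:
        names = meta.loc[meta["group"] == grp, "sample"]
        cols = [table.samples.index(s) for s in names]
        if not cols:
            raise ValueError(f"group {grp!r} absent from table")
        ok &= (table.total[:, cols] >= min_cov).sum(axis=1) >= min_samples_per_group
    return table.take(np.flatnonzero(ok))


def mask_sites(table: MethylTable, exclusion_intervals=None, snp_positions=None):
    """Drop sites inside any exclusion interval or at a SNP position.

    `exclusion_intervals` is an iterable of (chrom, start, end), 0-based
    half-open; `snp_positions` an iterable of (chrom, pos).
    """
    keep = np.ones(table.n_sites, dtype=bool)
    chrom = table.sites["chrom"].to_numpy()
    pos = table.sites["pos"].to_numpy()
    if exclusion_intervals is not None:
        for c, s, e in exclusion_intervals:
            keep &= ~((chrom == c) & (pos >= s) & (pos < e))
    if snp_positions is not None:
        snp = set(map(tuple, snp_positions))
        if snp:
            keep &= ~np.fromiter(
                ((c, p) in snp for c, p in zip(chrom, pos)),
                dtype=bool,
                count=table.n_sites,
            )
    return table.take(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# summaries


def context_summary(table: MethylTable, percent: bool = True) -> pd.DataFrame:
    """Mean site methylation per sample per context (unweighted across sites).

    Returns a context x sample frame, in percent by default. Contexts with
    zero covered sites are missing (NaN), not zero.
    """
    frac = table.fraction()
    ctx = table.sites["context"].astype(str).to_numpy()
    rows = {}
    for c in sorted(set(ctx)):
        sel = ctx == c
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[c] = np.nanmean(frac[sel], axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.samples)
    return out * 100.0 if percent else out


def level_histogram(
    table: MethylTable, context: str | None = None, bin_width: float = 10.0
) -> pd.DataFrame:
    """Distribution of site-level methylation per sample.

    Bins are [0,10), [10,20), ..., [90,100] percent by default; each
    sample's fractions sum to 1 over its covered sites. Empty input returns
    an empty frame.
    """
    t = table.select_context(context) if context else table
    if t.n_sites == 0:
        return pd.DataFrame()
    frac = t.fraction() * 100.0
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 2)]
    labels.append(f"[{edges[-2]:g},{edges[-1]:g}]")
    out = {}
    for j, s in enumerate(t.samples):
        v = frac[:, j]
        v = v[~np.isnan(v)]
        counts, _ = np.histogram(v, bins=edges)
        out[s] = counts / counts.sum() if counts.sum() else counts.astype(float)
    return pd.DataFrame(out, index=labels)


def profile_over_intervals(
    table: MethylTable,
    intervals: pd.DataFrame,
    flank_bp: int = 1200,
    n_bins: int = 10,
    n_flank_bins: int = 6,
    meta: pd.DataFrame | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean methylation profile over scaled intervals with fixed flanks.

    Each interval's body is split into `n_bins` equal parts; upstream and
    downstream flanks of `flank_bp` are split into `n_flank_bins` each.
    Minus-strand intervals (a `strand` column, if present) are reversed so
    bin 0 is always the 5' flank. Per-bin means are taken over sites, then
    averaged across intervals (NaN-aware) per sample; with `meta`, sample
    curves are averaged per group. Flanks extending past a chromosome edge
    are truncated and flagged via a `truncated` attribute on the result.
    """
    frac = table.fraction()
    pos = table.sites["pos"].to_numpy()
    chrom = table.sites["chrom"].to_numpy()
    total_bins = n_bins + 2 * n_flank_bins
    acc = np.zeros((total_bins, len(table.samples)))
    cnt = np.zeros((total_bins, len(table.samples)))
    truncated = False
    for _, iv in intervals.iterrows():
        s, e = int(iv["start"]), int(iv["end"])
        if e <= s:
            raise ValueError("degenerate interval")
        size = chrom_sizes.get(iv["chrom"]) if chrom_sizes else None
        lo, hi = s - flank_bp, e + flank_bp
        if lo < 0 or (size is not None and hi > size):
            truncated = True
            lo = max(lo, 0)
            if size is not None:
                hi = min(hi, size)
        sel = (chrom == iv["chrom"]) & (pos >= lo) & (pos < hi)
        if not sel.any():
            continue
        p = pos[sel]
        bins = np.empty(p.size, dtype=int)
        left = p < s
        right = p >= e
        body = ~(left | right)
        bins[left] = ((p[left] - (s - flank_bp)) * n_flank_bins // flank_bp).clip(
            0, n_flank_bins - 1
        )
        bins[body] = n_flank_bins + (p[body] - s) * n_bins // (e - s)
        bins[right] = (
            n_flank_bins
            + n_bins
            + ((p[right] - e) * n_flank_bins // flank_bp).clip(0, n_flank_bins - 1)
        )
        if str(iv.get("strand", "+")) == "-":
            bins = total_bins - 1 - bins
        v = frac[sel]
        ok = ~np.isnan(v)
        np.add.at(acc, bins, np.where(ok, v, 0.0))
        np.add.at(cnt, bins, ok.astype(float))
    with np.errstate(invalid="ignore"):
        prof = np.where(cnt > 0, acc / cnt, np.nan)
    out = pd.DataFrame(prof, columns=table.samples)
    if meta is not None:
        cols = {}
        for grp, g in meta.groupby("group"):
            cols[grp] = out[[s for s in g["sample"] if s in out.columns]].mean(axis=1)
        out = pd.DataFrame(cols)
    out.attrs["truncated"] = truncated
    return out


def state_methylation(table: MethylTable, consensus_map, meta=None) -> pd.DataFrame:
    """Mean site methylation per chromatin state per sample.

    `consensus_map` is an :class:`epidiff.chromstate.ConsensusMap`; sites in
    ambiguous/unlabelled bins are excluded from every state mean, and states
    absent from the map are omitted.
    """
    frac = table.fraction()
    labels = np.full(table.n_sites, -1, dtype=int)
    for chrom, g in table.sites.groupby("chrom", sort=False):
        if chrom not in consensus_map.labels:
            continue
        lab = consensus_map.labels[chrom]
        b = g["pos"].to_numpy() // consensus_map.bin_bp
        ok = b < lab.size
        labels[g.index.to_numpy()[ok]] = lab[b[ok]]
    rows = {}
    for st in sorted(set(labels[labels >= 0])):
        sel = labels == st
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[st] = np.nanmean(frac[sel], axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.samples)
    out.index.name = "state"
    return out
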