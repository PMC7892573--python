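"""Differentially methylated region calling.

The chain mirrors the smoothed two-group design standard for whole-genome
bisulfite data: per-sample local-regression smoothing of methylation
fractions, an unpaired Welch t test per site on the smoothed values, runs of
at least five consecutive significant sites (P < 0.001) with a consistent
sign and at least a 1% raw group difference become DMRs, and a per-region
ordinary least squares model of mean methylation on group, age and sex
retains only regions whose group term survives covariate adjustment.

`DifferentialMethylation` is the model-object facade over the functional
steps; its `fit()` returns a :class:`DMRResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .methylome import MethylTable
from .stats import welch_t

__all__ = [
    "smooth",
    "test_sites",
    "call_dmrs",
    "covariate_filter",
    "overlap_dmrs",
    "classify_by_regions",
    "DifferentialMethylation",
    "DMRResults",
]

DMR_COLUMNS = [
    "chrom", "start", "end", "context", "n_sites",
    "mean_diff", "areaStat", "direction", "covar_p",
]


def _empty_dmrs() -> pd.DataFrame:
    return pd.DataFrame(columns=DMR_COLUMNS)


# ---------------------------------------------------------------------------
# smoothing


def smooth(
    table: MethylTable,
    halfwidth_bp: int = 500,
    min_sites: int = 20,
    kernel: str = "tricube",
) -> np.ndarray:
    """Local-linear smoothing of per-sample methylation fractions.

    For each site, a window of +/- `halfwidth_bp` is widened symmetrically
    (in site counts) until it holds at least `min_sites` covered sites, and
    a tricube-weighted linear regression of fraction on position is
    evaluated at the site. Chromosomes with fewer than `min_sites` sites
    fall back to the raw fractions with a warning. Output is clipped to
    [0, 1]; samples' NaN (uncovered) sites are excluded from their own
    regressions and smoothed over.
    """
    if kernel != "tricube":
        raise ValueError("only the tricube kernel is supported")
    frac = table.fraction()
    out = np.full_like(frac, np.nan)
    chrom = table.sites["chrom"].to_numpy()
    pos = table.sites["pos"].to_numpy().astype(float)
    for c in pd.unique(chrom):
        rows = np.flatnonzero(chrom == c)
        x = pos[rows]
        y = frac[rows]
        n = rows.size
        if n < min_sites:
            warnings.warn(
                f"{c}: only {n} sites (< {min_sites}); raw fractions returned",
                stacklevel=2,
            )
            out[rows] = y
            continue
        lo = np.searchsorted(x, x - halfwidth_bp, side="left")
        hi = np.searchsorted(x, x + halfwidth_bp, side="right")
        for k in range(n):
            a, b = lo[k], hi[k]
            while b - a < min_sites:
                a = max(a - 1, 0)
                b = min(b + 1, n)
                if a == 0 and b == n:
                    break
            xi = x[a:b] - x[k]
            h = max(np.abs(xi).max(), 1.0)
            w = (1.0 - np.abs(xi / h) ** 3) ** 3
            yi = y[a:b]
            ok = ~np.isnan(yi)
            ww = np.where(ok, w[:, None], 0.0)
            yy = np.where(ok, yi, 0.0)
            sw = ww.sum(axis=0)
            swx = (ww * xi[:, None]).sum(axis=0)
            swx2 = (ww * (xi**2)[:, None]).sum(axis=0)
            swy = (ww * yy).sum(axis=0)
            swxy = (ww * yy * xi[:, None]).sum(axis=0)
            det = sw * swx2 - swx**2
            with np.errstate(invalid="ignore", divide="ignore"):
                fit = np.where(
                    det > 1e-12,
                    (swx2 * swy - swx * swxy) / det,
                    np.where(sw > 0, swy / np.maximum(sw, 1e-300), np.nan),
                )
            out[rows[k]] = fit
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# per-site tests


def test_sites(
    smoothed: np.ndarray, table: MethylTable, meta: pd.DataFrame
) -> pd.DataFrame:
    """Welch t test per site on smoothed per-sample values.

    Case (ELA) minus reference (C) differences; two-sided p values with
    Welch-Satterthwaite degrees of freedom. Returns a frame aligned with
    `table.sites` (chrom, pos, mean_ref, mean_case, diff, t, df, p).
    """
    groups = list(dict.fromkeys(meta["group"]))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ref, case = ("C", "ELA") if set(groups) == {"C", "ELA"} else groups
    cols_ref = [table.samples.index(s) for s in meta.loc[meta["group"] == ref, "sample"]]
    cols_case = [table.samples.index(s) for s in meta.loc[meta["group"] == case, "sample"]]
    a = smoothed[:, cols_case]
    b = smoothed[:, cols_ref]
    t, df, p = welch_t(a, b, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_case = np.nanmean(a, axis=1)
        mean_ref = np.nanmean(b, axis=1)
    return pd.DataFrame(
        {
            "chrom": table.sites["chrom"],
            "pos": table.sites["pos"],
            "mean_ref": mean_ref,
            "mean_case": mean_case,
            "diff": mean_case - mean_ref,
            "t": t,
            "df": df,
            "p": p,
        }
    )


# ---------------------------------------------------------------------------
# region calling


def call_dmrs(
    tests: pd.DataFrame,
    raw: MethylTable,
    meta: pd.DataFrame,
    context: str = "CG",
    p_thresh: float = 0.001,
    min_sites: int = 5,
    max_gap_bp: int = 300,
    min_diff: float = 0.01,
) -> pd.DataFrame:
    """Merge runs of consecutive significant sites into DMRs.

    A run is maximal over consecutive sites with p < `p_thresh`, a
    consistent difference sign and inter-site gaps <= `max_gap_bp`. Runs of
    at least `min_sites` sites whose absolute group difference of mean *raw*
    methylation is >= `min_diff` become DMRs spanning their member sites;
    areaStat is the sum of member t statistics.
    """
    ref_cols, case_cols = _group_columns(raw, meta)
    frac = raw.fraction()
    dmrs = []
    order = np.lexsort((tests["pos"].to_numpy(), tests["chrom"].to_numpy()))
    tests = tests.iloc[order].reset_index(drop=True)
    sig = (tests["p"].to_numpy() < p_thresh) & np.isfinite(tests["t"].to_numpy())
    sign = np.sign(tests["diff"].to_numpy())
    chrom = tests["chrom"].to_numpy()
    pos = tests["pos"].to_numpy()

    start_i = None
    for i in range(len(tests) + 1):
        boundary = (
            i == len(tests)
            or not sig[i]
            or sign[i] == 0
            or (
                start_i is not None
                and (
                    chrom[i] != chrom[i - 1]
                    or sign[i] != sign[i - 1]
                    or pos[i] - pos[i - 1] > max_gap_bp
                )
            )
        )
        if start_i is not None and boundary:
            _emit_run(
                dmrs, tests, raw, frac, ref_cols, case_cols,
                start_i, i, context, min_sites, min_diff, order,
            )
            start_i = None
        if i < len(tests) and sig[i] and sign[i] != 0 and start_i is None:
            start_i = i
    return pd.DataFrame(dmrs, columns=DMR_COLUMNS) if dmrs else _empty_dmrs()


def _group_columns(table: MethylTable, meta: pd.DataFrame):
    groups = list(dict.fromkeys(meta["group"]))
    ref, case = ("C", "ELA") if set(groups) == {"C", "ELA"} else groups
    ref_cols = [table.samples.index(s) for s in meta.loc[meta["group"] == ref, "sample"]]
    case_cols = [table.samples.index(s) for s in meta.loc[meta["group"] == case, "sample"]]
    return ref_cols, case_cols


def _emit_run(
    dmrs, tests, raw, frac, ref_cols, case_cols,
    start_i, end_i, context, min_sites, min_diff, order,
):
    n = end_i - start_i
    if n < min_sites:
        return
    rows = order[start_i:end_i]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_sample = np.nanmean(frac[rows], axis=0)
    diff = np.nanmean(per_sample[case_cols]) - np.nanmean(per_sample[ref_cols])
    if not np.isfinite(diff) or abs(diff) < min_diff:
        return
    area = float(tests["t"].to_numpy()[start_i:end_i].sum())
    dmrs.append(
        {
            "chrom": tests["chrom"].iat[start_i],
            "start": int(tests["pos"].iat[start_i]),
            "end": int(tests["pos"].iat[end_i - 1]) + 1,
            "context": context,
            "n_sites": int(n),
            "mean_diff": float(diff * 100.0),
            "areaStat": area,
            "direction": "HYPER" if diff > 0 else "HYPO",
            "covar_p": np.nan,
        }
    )


# ---------------------------------------------------------------------------
# covariate retention


def covariate_filter(
    dmrs: pd.DataFrame,
    raw: MethylTable,
    meta: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Retain DMRs whose group effect survives adjustment for age and sex.

    Per DMR, ordinary least squares of per-sample mean raw methylation over
    the region on group + age + sex; the group coefficient's p value is
    recorded as `covar_p` and the DMR retained iff covar_p < `alpha`.
    Constant covariates (e.g. a single-sex cohort) are dropped with a
    warning rather than producing a rank-deficient design.
    """
    if dmrs.empty:
        return dmrs.copy()
    chrom = raw.sites["chrom"].to_numpy()
    pos = raw.sites["pos"].to_numpy()
    frac = raw.fraction()
    meta = meta.set_index("sample").loc[raw.samples].reset_index()
    group = (meta["group"] == meta["group"].unique()[-1]).astype(float)
    cov = {"group": group.to_numpy()}
    for name in ("age", "sex"):
        v = meta[name]
        v = pd.factorize(v)[0].astype(float) if v.dtype == object else v.to_numpy(float)
        if np.unique(v).size < 2:
            warnings.warn(f"covariate {name!r} is constant; dropped", stacklevel=2)
            continue
        cov[name] = v
    X = sm.add_constant(pd.DataFrame(cov))
    out = dmrs.copy().reset_index(drop=True)
    pvals = np.empty(len(out))
    for i, d in out.iterrows():
        rows = np.flatnonzero(
            (chrom == d["chrom"]) & (pos >= d["start"]) & (pos < d["end"])
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            y = np.nanmean(frac[rows], axis=0)
        ok = ~np.isnan(y)
        fit = sm.OLS(y[ok], X[ok]).fit()
        pvals[i] = fit.pvalues["group"]
    out["covar_p"] = pvals
    return out[out["covar_p"] < alpha].reset_index(drop=True)


# ---------------------------------------------------------------------------
# region set utilities


def overlap_dmrs(set_a: pd.DataFrame, set_b: pd.DataFrame) -> pd.DataFrame:
    """All pairs of regions from the two sets sharing >= 1 bp (symmetric)."""
    pairs = []
    for ia, a in set_a.reset_index(drop=True).iterrows():
        for ib, b in set_b.reset_index(drop=True).iterrows():
            if (
                a["chrom"] == b["chrom"]
                and a["start"] < b["end"]
                and b["start"] < a["end"]
            ):
                pairs.append((ia, ib))
    return pd.DataFrame(pairs, columns=["index_a", "index_b"])


def classify_by_regions(
    dmrs: pd.DataFrame,
    classes: dict[str, pd.DataFrame],
    other_label: str = "other",
) -> pd.DataFrame:
    """Assign each DMR to a region class by the majority-bp rule.

    `classes` maps a label to a frame of (chrom, start, end); intervals
    within a label must be disjoint. Ties are broken by the order of
    `classes` (a precedence order); a DMR overlapping nothing is assigned
    `other_label`. Returns the DMR frame with a `region_class` column.
    """
    out = dmrs.copy().reset_index(drop=True)
    labels = []
    for _, d in out.iterrows():
        best, best_bp = other_label, 0
        for label, ivs in classes.items():
            sub = ivs[ivs["chrom"] == d["chrom"]]
            starts = np.maximum(sub["start"].to_numpy(), d["start"])
            ends = np.minimum(sub["end"].to_numpy(), d["end"])
            bp = int(np.maximum(ends - starts, 0).sum())
            if bp > best_bp:
                best, best_bp = label, bp
        labels.append(best)
    out["region_class"] = labels
    return out


# ---------------------------------------------------------------------------
# model facade


@dataclass
class DMRResults:
    """Fit results: called regions, per-site tests and the inputs used."""

    dmrs: pd.DataFrame
    site_tests: pd.DataFrame
    context: str
    params: dict = field(default_factory=dict)
    n_dropped_by_covariates: int = 0

    def summary(self) -> str:
        lines = [
            f"Differential methylation ({self.context} context)",
            f"  sites tested:          {len(self.site_tests)}",
            f"  DMRs called:           {len(self.dmrs)}",
            f"  dropped by covariates: {self.n_dropped_by_covariates}",
        ]
        if len(self.dmrs):
            hyper = int((self.dmrs["direction"] == "HYPER").sum())
            lines += [
                f"  hyper / hypo:          {hyper} / {len(self.dmrs) - hyper}",
                f"  mean |diff| (%):       {self.dmrs['mean_diff'].abs().mean():.2f}",
                f"  mean n_sites:          {self.dmrs['n_sites'].mean():.1f}",
            ]
        for k, v in self.params.items():
            lines.append(f"  {k} = {v}")
        return "\n".join(lines)

    def to_bed(self, path) -> None:
        """Write DMRs as BED6+ (name, areaStat score, '.' strand, extras)."""
        with open(path, "w") as fh:
            for i, d in self.dmrs.reset_index(drop=True).iterrows():
                fh.write(
                    f"{d['chrom']}\t{d['start']}\t{d['end']}\tDMR{i:05d}\t"
                    f"{d['areaStat']:.3f}\t.\t{d['context']}\t{d['n_sites']}\t"
                    f"{d['mean_diff']:.4f}\t{d['covar_p']}\n"
                )


class DifferentialMethylation:
    """Two-group differential methylation model for one cytosine context.

    Parameters
    ----------
    table
        Coverage-filtered :class:`MethylTable` (strand-merged for CG).
    meta
        Sample metadata with sample, group, age, sex.
    context
        "CG" or "CAC"; selects rows and labels the output.
    """

    def __init__(self, table: MethylTable, meta: pd.DataFrame, context: str = "CG"):
        self.table = table.select_context(context)
        self.meta = meta
        self.context = context

    def fit(
        self,
        p_thresh: float = 0.001,
        min_sites: int = 5,
        max_gap_bp: int = 300,
        min_diff: float = 0.01,
        halfwidth_bp: int = 500,
        smooth_min_sites: int = 20,
        adjust_covariates: bool = True,
        alpha: float = 0.05,
    ) -> DMRResults:
        sm_vals = smooth(self.table, halfwidth_bp, smooth_min_sites)
        tests = test_sites(sm_vals, self.table, self.meta)
        dmrs = call_dmrs(
            tests, self.table, self.meta, self.context,
            p_thresh, min_sites, max_gap_bp, min_diff,
        )
        dropped = 0
        if adjust_covariates and {"age", "sex"} <= set(self.meta.columns):
            kept = covariate_filter(dmrs, self.table, self.meta, alpha)
            dropped = len(dmrs) - len(kept)
            dmrs = kept
        return DMRResults(
            dmrs,
            tests,
            self.context,
            params={
                "p_thresh": p_thresh, "min_sites": min_sites,
                "max_gap_bp": max_gap_bp, "min_diff": min_diff,
                "halfwidth_bp": halfwidth_bp, "alpha": alpha,
            },
            n_dropped_by_covariates=dropped,
        )
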