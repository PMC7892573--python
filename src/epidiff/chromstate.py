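"""Consensus chromatin-state maps and group state transitions.

Per-sample 200-bp state segmentations are rasterised onto a shared bin
grid; a consensus map keeps the modal state of each bin only where enough
samples agree (6/11 for the cohort-wide map; a 70% within-group fraction,
i.e. 3/4 and 5/7 for the reference design, for the two group maps). Bins
where both group maps are confidently labelled but disagree are state
transitions; adjacent bins with the same (from, to) pair merge into
regions, which are tabulated into a K x K transition table and annotated to
genomic features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AMBIGUOUS",
    "MISSING",
    "StateTracks",
    "ConsensusMap",
    "load_tracks",
    "consensus",
    "group_maps",
    "transitions",
    "tabulate",
    "annotate_features",
    "overlap_enrichment",
    "StateTransitionModel",
    "TransitionResults",
]

MISSING = -2
AMBIGUOUS = -1

FEATURE_LABELS = [
    "ProximalPromoter",
    "Promoter1-3k",
    "GeneBody",
    "ImmediateDownstream",
    "GeneDesert",
    "OtherIntergenic",
]


@dataclass
class StateTracks:
    """Per-sample per-bin state labels (0-based states; MISSING = -2)."""

    samples: list[str]
    groups: list[str]
    bin_bp: int
    labels: dict[str, np.ndarray]  # chrom -> (n_samples, n_bins)
    n_states: int

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, names) -> "StateTracks":
        idx = [self.samples.index(s) for s in names]
        return StateTracks(
            [self.samples[i] for i in idx],
            [self.groups[i] for i in idx],
            self.bin_bp,
            {c: lab[idx] for c, lab in self.labels.items()},
            self.n_states,
        )


@dataclass
class ConsensusMap:
    """Per-bin consensus labels with the supporting agreement counts."""

    bin_bp: int
    labels: dict[str, np.ndarray]  # chrom -> (n_bins,), AMBIGUOUS where unmet
    agreement: dict[str, np.ndarray]
    n_states: int

    def to_bed(self, path, state_names=None) -> None:
        with open(path, "w") as fh:
            for chrom, lab in self.labels.items():
                for s, e, v in _runs(lab):
                    if v < 0:
                        continue
                    name = state_names[v] if state_names else f"S{v + 1}"
                    fh.write(
                        f"{chrom}\t{s * self.bin_bp}\t{e * self.bin_bp}\t{name}\n"
                    )


def _runs(arr: np.ndarray):
    """Yield (start_bin, end_bin, value) runs of a 1-d label array."""
    if arr.size == 0:
        return
    edges = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [arr.size]])
    for s, e in zip(starts, ends):
        yield int(s), int(e), int(arr[s])


# ---------------------------------------------------------------------------
# loading


def load_tracks(
    paths: dict[str, str],
    chrom_sizes: dict[str, int],
    bin_bp: int = 200,
    state_names: list[str] | None = None,
    groups: dict[str, str] | None = None,
) -> StateTracks:
    """Load per-sample BED4 segmentations onto a shared bin grid.

    `paths` maps sample id -> BED4 file (chrom, start, end, state label).
    Off-grid intervals are rasterised by majority-bp: each bin takes the
    state covering most of it. Gaps stay MISSING. State labels are either
    matched against `state_names` or collected across all files (sorted);
    an unknown label (when `state_names` is given) raises ValueError.
    """
    beds = {
        s: pd.read_csv(
            p, sep="\t", header=None, names=["chrom", "start", "end", "state"],
            dtype={"chrom": str, "state": str},
        )
        for s, p in paths.items()
    }
    if state_names is None:
        state_names = sorted({st for df in beds.values() for st in df["state"]})
    index = {name: i for i, name in enumerate(state_names)}

    samples = list(beds)
    labels = {
        c: np.full((len(samples), size // bin_bp), MISSING, dtype=np.int16)
        for c, size in chrom_sizes.items()
    }
    for si, (s, df) in enumerate(beds.items()):
        unknown = set(df["state"]) - set(index)
        if unknown:
            raise ValueError(f"{s}: unknown state labels {sorted(unknown)}")
        for chrom, g in df.groupby("chrom", sort=False):
            if chrom not in labels:
                continue
            n_bins = labels[chrom].shape[1]
            cover = np.zeros((len(state_names), n_bins), dtype=np.int64)
            for _, iv in g.iterrows():
                st = index[iv["state"]]
                b0 = int(iv["start"]) // bin_bp
                b1 = min((int(iv["end"]) + bin_bp - 1) // bin_bp, n_bins)
                for b in range(b0, b1):
                    lo = max(int(iv["start"]), b * bin_bp)
                    hi = min(int(iv["end"]), (b + 1) * bin_bp)
                    cover[st, b] += max(hi - lo, 0)
            covered = cover.sum(axis=0) * 2 > bin_bp  # majority of the bin
            best = cover.argmax(axis=0)
            row = labels[chrom][si]
            row[covered] = best[covered]
    tracks = StateTracks(
        samples,
        [groups.get(s, "") for s in samples] if groups else [""] * len(samples),
        bin_bp,
        labels,
        len(state_names),
    )
    tracks.state_names = state_names
    return tracks


# ---------------------------------------------------------------------------
# consensus and transitions


def consensus(tracks: StateTracks, min_agree: int) -> ConsensusMap:
    """Per-bin modal state where its count >= `min_agree`, else AMBIGUOUS.

    MISSING labels are excluded from the vote counts; a tie at or above the
    threshold is conservative (AMBIGUOUS) — with min_agree > n/2 ties are
    impossible, and for small group maps determinism matters more than a
    forced call.
    """
    if min_agree > tracks.n_samples:
        raise ValueError(
            f"min_agree={min_agree} exceeds {tracks.n_samples} tracks"
        )
    out_labels = {}
    out_agree = {}
    for chrom, lab in tracks.labels.items():
        counts = np.zeros((tracks.n_states, lab.shape[1]), dtype=np.int32)
        for st in range(tracks.n_states):
            counts[st] = (lab == st).sum(axis=0)
        top = counts.max(axis=0)
        modal = counts.argmax(axis=0)
        tied = (counts == top).sum(axis=0) > 1
        ok = (top >= min_agree) & ~tied
        res = np.where(ok, modal, AMBIGUOUS).astype(np.int16)
        out_labels[chrom] = res
        out_agree[chrom] = top
    return ConsensusMap(tracks.bin_bp, out_labels, out_agree, tracks.n_states)


def group_maps(
    tracks_ref: StateTracks,
    tracks_case: StateTracks,
    min_agree_frac: float = 0.70,
):
    """Group consensus maps at threshold ceil(frac x n) per group.

    For a 4 + 7 design at 70% this is the 3/4 and 5/7 rule.
    """
    if tracks_ref.n_samples == 0 or tracks_case.n_samples == 0:
        raise ValueError("both groups need at least one track")
    thr_ref = int(np.ceil(min_agree_frac * tracks_ref.n_samples))
    thr_case = int(np.ceil(min_agree_frac * tracks_case.n_samples))
    return consensus(tracks_ref, thr_ref), consensus(tracks_case, thr_case)


def transitions(map_ref: ConsensusMap, map_case: ConsensusMap) -> pd.DataFrame:
    """Regions where both group maps are labelled but disagree.

    Adjacent bins with the same (state_from, state_to) pair merge into one
    region. Bins AMBIGUOUS or MISSING in either map are excluded. Returns
    chrom, start, end (bp), state_from, state_to, n_bins.
    """
    if map_ref.bin_bp != map_case.bin_bp or set(map_ref.labels) != set(
        map_case.labels
    ):
        raise ValueError("maps are on different bin grids")
    bb = map_ref.bin_bp
    rows = []
    for chrom in map_ref.labels:
        a = map_ref.labels[chrom]
        b = map_case.labels[chrom]
        if a.size != b.size:
            raise ValueError(f"{chrom}: bin grids differ in length")
        diff = (a >= 0) & (b >= 0) & (a != b)
        # encode (from,to) per differing bin; -1 elsewhere breaks runs
        code = np.where(diff, a.astype(np.int64) * map_ref.n_states + b, -1)
        for s, e, v in _runs(code):
            if v < 0:
                continue
            rows.append(
                (
                    chrom,
                    s * bb,
                    e * bb,
                    int(v // map_ref.n_states),
                    int(v % map_ref.n_states),
                    e - s,
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "state_from", "state_to", "n_bins"]
    )


def tabulate(trans: pd.DataFrame, n_states: int, unit: str = "regions"):
    """K x K transition-type table with totals and percentages.

    Returns (counts, percent, info): `counts` is a K x K frame (rows =
    reference state, columns = case state, diagonal zero) counting either
    merged `regions` or differing `bins`; `percent` the same cells as a
    percentage of the total; `info` holds total, observed_types and
    possible_types = K(K-1).
    """
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    w = trans["n_bins"] if unit == "bins" else np.ones(len(trans), dtype=int)
    for (f, t), wt in zip(
        zip(trans["state_from"], trans["state_to"]), np.asarray(w)
    ):
        counts[f, t] += int(wt)
    total = int(counts.sum())
    idx = [f"S{i + 1}" for i in range(n_states)]
    cdf = pd.DataFrame(counts, index=idx, columns=idx)
    pdf = cdf / total * 100.0 if total else cdf.astype(float)
    info = {
        "total": total,
        "observed_types": int((counts > 0).sum()),
        "possible_types": n_states * (n_states - 1),
        "row_total": cdf.sum(axis=1),
        "col_total": cdf.sum(axis=0),
        "unit": unit,
    }
    return cdf, pdf, info


# ---------------------------------------------------------------------------
# feature annotation and overlap enrichment


def annotate_features(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    desert_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Label each region by its midpoint's genomic feature.

    Precedence: ProximalPromoter (<= 1 kb upstream of a TSS) >
    Promoter1-3k (1-3 kb upstream) > GeneBody > ImmediateDownstream (<= 1 kb
    past the TES) > intergenic (GeneDesert beyond `desert_bp` from any gene,
    else OtherIntergenic). Upstream is strand-aware. Adds a `feature`
    column; `.attrs["distribution"]` holds the label fractions.
    """
    out = regions.copy().reset_index(drop=True)
    labels = []
    for _, r in out.iterrows():
        mid = (int(r["start"]) + int(r["end"])) // 2
        g = genes[genes["chrom"] == r["chrom"]]
        label = "OtherIntergenic"
        if g.empty:
            label = "GeneDesert"
        else:
            tss = g["tss"].to_numpy()
            plus = (g["strand"] == "+").to_numpy()
            updist = np.where(plus, tss - mid, mid - tss)  # >0 means upstream
            in_body = (g["start"].to_numpy() <= mid) & (mid < g["end"].to_numpy())
            tes = g["tes"].to_numpy()
            downdist = np.where(plus, mid - tes, tes - mid)
            if ((updist > 0) & (updist <= 1000)).any():
                label = "ProximalPromoter"
            elif ((updist > 1000) & (updist <= 3000)).any():
                label = "Promoter1-3k"
            elif in_body.any():
                label = "GeneBody"
            elif ((downdist > 0) & (downdist <= 1000)).any():
                label = "ImmediateDownstream"
            else:
                gene_dist = np.minimum(
                    np.abs(mid - g["start"].to_numpy()),
                    np.abs(mid - g["end"].to_numpy()),
                )
                label = "GeneDesert" if gene_dist.min() > desert_bp else "OtherIntergenic"
        labels.append(label)
    out["feature"] = labels
    dist = out["feature"].value_counts(normalize=True)
    out.attrs["distribution"] = dist
    return out


def overlap_enrichment(
    cmap: ConsensusMap, features: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Fold enrichment of each (state, feature-set) overlap by bp accounting.

    fold = [bp(state n feature) / bp(genome)] /
           ([bp(state) / bp(genome)] x [bp(feature) / bp(genome)]).
    States or features with zero bp give NaN (reported missing).
    """
    genome_bp = sum(lab.size for lab in cmap.labels.values()) * cmap.bin_bp
    state_bp = np.zeros(cmap.n_states, dtype=np.int64)
    for lab in cmap.labels.values():
        for st in range(cmap.n_states):
            state_bp[st] += int((lab == st).sum()) * cmap.bin_bp

    out = {}
    for fname, ivs in features.items():
        feat_bp = 0
        inter = np.zeros(cmap.n_states, dtype=np.int64)
        for _, iv in ivs.iterrows():
            chrom = iv["chrom"]
            if chrom not in cmap.labels:
                continue
            lab = cmap.labels[chrom]
            s, e = int(iv["start"]), int(iv["end"])
            e = min(e, lab.size * cmap.bin_bp)
            s = max(s, 0)
            if e <= s:
                continue
            feat_bp += e - s
            b0, b1 = s // cmap.bin_bp, (e + cmap.bin_bp - 1) // cmap.bin_bp
            for b in range(b0, b1):
                st = lab[b]
                if st < 0:
                    continue
                lo = max(s, b * cmap.bin_bp)
                hi = min(e, (b + 1) * cmap.bin_bp)
                inter[st] += hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            fold = (inter / genome_bp) / (
                (state_bp / genome_bp) * (feat_bp / genome_bp)
            )
        fold[state_bp == 0] = np.nan
        if feat_bp == 0:
            fold[:] = np.nan
        out[fname] = fold
    return pd.DataFrame(out, index=[f"S{i + 1}" for i in range(cmap.n_states)])


# ---------------------------------------------------------------------------
# model facade


@dataclass
class TransitionResults:
    """Group maps, transition regions and their tabulation."""

    map_ref: ConsensusMap
    map_case: ConsensusMap
    regions: pd.DataFrame
    counts: pd.DataFrame
    percent: pd.DataFrame
    info: dict = field(default_factory=dict)

    def summary(self) -> str:
        return "\n".join(
            [
                "Chromatin-state transitions",
                f"  transition regions:  {self.info['total']}",
                f"  observed ST types:   {self.info['observed_types']}"
                f" / {self.info['possible_types']} possible",
                f"  unit:                {self.info['unit']}",
            ]
        )


class StateTransitionModel:
    """Two-group chromatin-state comparison from per-sample tracks."""

    def __init__(self, tracks_ref: StateTracks, tracks_case: StateTracks):
        self.tracks_ref = tracks_ref
        self.tracks_case = tracks_case

    @classmethod
    def from_tracks(cls, tracks: StateTracks, ref_group: str, case_group: str):
        ref = tracks.subset(
            [s for s, g in zip(tracks.samples, tracks.groups) if g == ref_group]
        )
        case = tracks.subset(
            [s for s, g in zip(tracks.samples, tracks.groups) if g == case_group]
        )
        return cls(ref, case)

    def fit(self, min_agree_frac: float = 0.70, unit: str = "regions"):
        m_ref, m_case = group_maps(self.tracks_ref, self.tracks_case, min_agree_frac)
        regs = transitions(m_ref, m_case)
        counts, pct, info = tabulate(regs, self.tracks_ref.n_states, unit=unit)
        return TransitionResults(m_ref, m_case, regs, counts, pct, info)
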