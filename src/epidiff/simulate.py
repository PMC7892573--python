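"""Synthetic two-group epigenome cohorts with known ground truth.

Generates, from a single seeded configuration:

* a random CpG-depleted genome with gene annotations and every cytosine
  enumerated in its three-letter (CNN) sequence context on both strands;
* per-sample bisulfite-style methylation count tables, beta-binomial around
  context-specific baselines (CG high and unimodal, CAC low with a minority
  component between 10 and 20%), with spiked differentially methylated
  regions per context and optional age-confounded regions;
* per-sample 200-bp chromatin-state tracks around a latent baseline map with
  independent per-bin mislabelling, plus group-switched spiked segments;
* a pair of correlated signed-significance gene rankings;
* flat gene-set collections in which designated terms are placed over the
  spiked regions.

Everything a downstream caller should recover is recorded in a
:class:`TruthSet`. One named RNG stream per output class keeps the streams
independent: adding one output class never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GenomeModel",
    "TruthSet",
    "make_genome",
    "make_methylomes",
    "make_state_tracks",
    "make_ranked_lists",
    "make_gene_sets",
    "write_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G on byte codes

# 16 cytosine contexts in lexicographic order of the two trailing bases
CONTEXTS = tuple("C" + a + b for a in "ACGT" for b in "ACGT")

# stream labels -> fixed sub-seed component (never reordered)
_STREAMS = {"genome": 0, "methylomes": 1, "tracks": 2, "lists": 3, "genesets": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the reference design: 17 reference (C) vs 21 case (ELA)
    methylomes, 4 vs 7 chromatin-state tracks, a 10-state model, CG
    methylation near 81% and CAC near 4.1% with a 10-20% minority component,
    mean sequencing depth 10 and spiked 8-site DMRs shifting the case mean
    by 10 percentage points.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 1_000_000
    n_genes: int = 80
    n_samples_per_group: tuple[int, int] = (17, 21)
    n_tracks_per_group: tuple[int, int] = (4, 7)
    cg_baseline_mean: float = 0.81
    cac_baseline_mean: float = 0.041
    cac_methylated_minority_frac: float = 0.15
    coverage_mean: float = 10.0
    coverage_shape: float = 8.0
    overdispersion: float = 0.02
    n_spiked_dmrs_per_context: int = 50
    dmr_delta: float = 0.10
    dmr_width_sites: int = 8
    n_target_windows: int = 3
    target_window_bp: int = 100_000
    spike_cluster_frac: float = 0.75
    age_effect_slope: float = 0.008
    n_confounded_regions: int = 0
    age_gap_years: float = 0.0
    n_states: int = 10
    state_noise_eps: float = 0.1
    n_spiked_transitions: int = 20
    spiked_transition_bins: int = 5
    state_segment_mean_bins: int = 10
    bin_bp: int = 200
    ranked_list_corr: float = 0.5
    gc_content: float = 0.40
    cpg_depletion: float = 0.85

    def __post_init__(self) -> None:
        for name in (
            "cg_baseline_mean",
            "cac_baseline_mean",
            "cac_methylated_minority_frac",
            "overdispersion",
            "dmr_delta",
            "spike_cluster_frac",
            "state_noise_eps",
            "gc_content",
            "cpg_depletion",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dmr_width_sites < 5:
            raise ValueError("dmr_width_sites must be >= 5")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if not -1.0 <= self.ranked_list_corr <= 1.0:
            raise ValueError("ranked_list_corr outside [-1, 1]")


@dataclass
class GenomeModel:
    """A synthetic genome: sequences, gene model and enumerated cytosines."""

    chrom_sizes: dict[str, int]
    sequences: dict[str, np.ndarray]  # uint8 ASCII codes
    genes: pd.DataFrame  # gene_id, chrom, strand, start, end, tss, tes
    cytosines: pd.DataFrame  # chrom, pos, strand, context (Categorical)

    def sequence_str(self, chrom: str) -> str:
        return self.sequences[chrom].tobytes().decode("ascii")


@dataclass
class TruthSet:
    """Ground truth of every spiked feature, JSON-serialisable."""

    true_dmrs: list[dict] = field(default_factory=list)
    true_transitions: list[dict] = field(default_factory=list)
    confounded_regions: list[dict] = field(default_factory=list)
    enriched_terms: list[str] = field(default_factory=list)
    target_windows: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# genome


def make_genome(cfg: SimConfig) -> GenomeModel:
    """Draw a CpG-depleted random genome and enumerate all cytosine contexts.

    The sequence is i.i.d. with GC content `cfg.gc_content`, after which a
    fraction `cfg.cpg_depletion` of CpG dyads have their G mutated away,
    reproducing the CpG depletion (and hence realistic CG-site sparsity) of
    mammalian genomes. Gene placement requires roughly 10 kb of room per
    gene; shorter chromosomes raise ValueError.
    """
    rng = _rng(cfg.seed, "genome")
    at = (1.0 - cfg.gc_content) / 2.0
    gc = cfg.gc_content / 2.0
    probs = [at, gc, gc, at]

    sizes: dict[str, int] = {}
    seqs: dict[str, np.ndarray] = {}
    for c in range(cfg.n_chrom):
        name = f"chr{c + 1}"
        seq = rng.choice(_BASES, size=cfg.chrom_len, p=probs)
        cg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
        hit = cg[rng.random(cg.size) < cfg.cpg_depletion]
        seq[hit + 1] = rng.choice(
            np.frombuffer(b"AT", dtype=np.uint8), size=hit.size
        )
        sizes[name] = cfg.chrom_len
        seqs[name] = seq

    genes = _place_genes(cfg, rng, sizes)
    cyt = pd.concat(
        [_enumerate_cytosines(name, seq) for name, seq in seqs.items()],
        ignore_index=True,
    )
    return GenomeModel(sizes, seqs, genes, cyt)


def _place_genes(cfg, rng, sizes) -> pd.DataFrame:
    rows = []
    if cfg.n_genes:
        per_chrom = np.array_split(np.arange(cfg.n_genes), cfg.n_chrom)
        for (name, size), idx in zip(sizes.items(), per_chrom):
            n = len(idx)
            if n == 0:
                continue
            if size < 10_000 * n:
                raise ValueError(
                    f"{name} ({size} bp) too short for {n} genes"
                )
            starts = np.sort(rng.choice(size - 31_000, size=n, replace=False))
            lengths = rng.integers(5_000, 30_000, size=n)
            strands = rng.choice(["+", "-"], size=n)
            for g, s, ln, st in zip(idx, starts, lengths, strands):
                end = min(int(s) + int(ln), size)
                tss, tes = (int(s), end) if st == "+" else (end, int(s))
                rows.append((f"G{g:04d}", name, st, int(s), end, tss, tes))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss", "tes"]
    )


def _enumerate_cytosines(name: str, seq: np.ndarray) -> pd.DataFrame:
    n = seq.size
    b1 = np.searchsorted(_BASES, seq)  # base index 0..3 (A,C,G,T)

    plus = np.flatnonzero(seq == ord("C"))
    plus = plus[plus + 2 < n]  # truncated triplets dropped
    ctx_plus = 4 * b1[plus + 1] + b1[plus + 2]

    minus = np.flatnonzero(seq == ord("G"))
    minus = minus[minus - 2 >= 0]
    # 5'->3' on the minus strand: complement of pos-1, pos-2
    ctx_minus = 4 * (3 - b1[minus - 1]) + (3 - b1[minus - 2])

    df = pd.DataFrame(
        {
            "chrom": name,
            "pos": np.concatenate([plus, minus]),
            "strand": np.repeat(["+", "-"], [plus.size, minus.size]),
            "context": pd.Categorical.from_codes(
                np.concatenate([ctx_plus, ctx_minus]).astype(np.int8),
                categories=list(CONTEXTS),
            ),
        }
    )
    return df.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# methylomes

_NONCG_BASELINES = {
    "CAC": None,  # mixture, handled explicitly
    "CTC": 0.018, "CAG": 0.016, "CAT": 0.013, "CAA": 0.011,
}
_OTHER_BASELINE = 0.003


def make_methylomes(cfg: SimConfig, genome: GenomeModel, contexts=("CG", "CAC")):
    """Draw per-sample beta-binomial methylation counts with spiked DMRs.

    Parameters
    ----------
    contexts
        Context groups to emit: "CG" covers all four CGN contexts (the two
        cytosines of a dyad share one latent methylation level), "CAC" the
        strand-asymmetric trinucleotide, "all" every one of the 16.

    Returns
    -------
    table : :class:`epidiff.methylome.MethylTable`
        Unmerged per-cytosine counts across all samples.
    meta : DataFrame with sample, group, age, sex.
    truth : :class:`TruthSet`
    """
    from .methylome import MethylTable

    rng = _rng(cfg.seed, "methylomes")
    n_ref, n_case = cfg.n_samples_per_group
    n = n_ref + n_case
    meta = _sample_metadata(cfg, rng, n_ref, n_case)
    case_mask = (meta["group"] == "ELA").to_numpy()

    if contexts == "all" or "all" in contexts:
        wanted = set(CONTEXTS)
    else:
        wanted = set()
        for c in contexts:
            if c == "CG":
                wanted.update(x for x in CONTEXTS if x.startswith("CG"))
            elif c in CONTEXTS:
                wanted.add(c)
            else:
                raise ValueError(f"unknown context group {c!r}")

    cyt = genome.cytosines
    sites = cyt[cyt["context"].isin(sorted(wanted))].reset_index(drop=True)
    sites = sites.sort_values(["chrom", "pos", "strand"], kind="stable")
    sites = sites.reset_index(drop=True)

    mu_site = _baseline_means(cfg, rng, sites)
    truth = TruthSet()
    mu = np.broadcast_to(mu_site[:, None], (len(sites), n)).copy()
    _spike_dmrs(cfg, rng, sites, mu, case_mask, truth)
    _confound_regions(cfg, rng, sites, mu, meta, truth)

    np.clip(mu, 1e-4, 1 - 1e-4, out=mu)
    total = rng.negative_binomial(
        cfg.coverage_shape,
        cfg.coverage_shape / (cfg.coverage_shape + cfg.coverage_mean),
        size=mu.shape,
    ).astype(np.int32)
    ab = (1.0 - cfg.overdispersion) / cfg.overdispersion
    p = rng.beta(mu * ab, (1.0 - mu) * ab)
    meth = rng.binomial(total, p).astype(np.int32)

    table = MethylTable(sites[["chrom", "pos", "strand", "context"]].copy(),
                        meth, total, list(meta["sample"]))
    return table, meta, truth


def _sample_metadata(cfg, rng, n_ref, n_case) -> pd.DataFrame:
    gap = cfg.age_gap_years
    age_ref = rng.uniform(15.0, 70.0 - gap, size=n_ref)
    age_case = rng.uniform(15.0 + gap, 70.0, size=n_case)
    rows = []
    for i in range(n_ref):
        rows.append((f"C{i + 1:02d}", "C", age_ref[i], "MF"[i % 2]))
    for i in range(n_case):
        rows.append((f"E{i + 1:02d}", "ELA", age_case[i], "MF"[i % 2]))
    return pd.DataFrame(rows, columns=["sample", "group", "age", "sex"])


def _baseline_means(cfg, rng, sites) -> np.ndarray:
    ctx = sites["context"].astype(str).to_numpy(dtype="U3")
    mu = np.full(len(sites), _OTHER_BASELINE)
    mu[np.char.startswith(ctx, "CG")] = cfg.cg_baseline_mean
    for name, base in _NONCG_BASELINES.items():
        if base is not None:
            mu[ctx == name] = base
    cac = np.flatnonzero(ctx == "CAC")
    if cac.size:
        f = cfg.cac_methylated_minority_frac
        minority = rng.random(cac.size) < f
        # majority component balances the 10-20% minority so the genome-wide
        # mean equals cac_baseline_mean
        lo = max((cfg.cac_baseline_mean - 0.15 * f) / (1.0 - f), 1e-3)
        mu[cac] = lo
        mu[cac[minority]] = rng.uniform(0.10, 0.20, size=int(minority.sum()))
    return mu


def _dyad_units(sites: pd.DataFrame, context: str):
    """Group site row-indices into spike units for one context.

    CG units are strand dyads (plus C at i, minus C at i+1) keyed by the
    plus-strand position; CAC units are single stranded sites. Returns, per
    chromosome, (unit start positions, list of row-index arrays).
    """
    out = {}
    ctx = sites["context"].astype(str)
    if context == "CG":
        mask = ctx.str.startswith("CG")
    else:
        mask = ctx == context
    sub = sites[mask]
    for chrom, g in sub.groupby("chrom", observed=True, sort=True):
        if context != "CG":
            out[chrom] = (g["pos"].to_numpy(), [np.array([i]) for i in g.index])
            continue
        pos = g["pos"].to_numpy()
        strand = g["strand"].to_numpy()
        idx = g.index.to_numpy()
        dyad_pos = np.where(strand == "+", pos, pos - 1)
        units: dict[int, list[int]] = {}
        for dp, i in zip(dyad_pos, idx):
            units.setdefault(int(dp), []).append(int(i))
        keys = np.array(sorted(units))
        out[chrom] = (keys, [np.array(units[k]) for k in keys])
    return out


def _pick_runs(rng, units_by_chrom, n_runs, width, taken,
               min_gap_bp=2_000, windows=None):
    """Pick non-overlapping runs of `width` consecutive units, avoiding the
    intervals already in `taken` (list of (chrom, start, end)).

    With `windows` (list of (chrom, start, end)), every run must fall
    entirely inside one of them.
    """
    runs = []
    chroms = sorted(units_by_chrom)
    attempts = 0
    while len(runs) < n_runs and attempts < 200 * max(n_runs, 1):
        attempts += 1
        if windows:
            wc, ws, we = windows[int(rng.integers(len(windows)))]
            if wc not in units_by_chrom:
                continue
            pos, idx_lists = units_by_chrom[wc]
            lo = int(np.searchsorted(pos, ws, side="left"))
            hi = int(np.searchsorted(pos, we, side="right"))
            if hi - lo < width:
                continue
            s = lo + int(rng.integers(hi - lo - width + 1))
            chrom = wc
            if int(pos[s + width - 1]) + 2 > we:
                continue
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos, idx_lists = units_by_chrom[chrom]
            if pos.size < width:
                continue
            s = int(rng.integers(pos.size - width + 1))
        start, end = int(pos[s]), int(pos[s + width - 1]) + 2
        clash = any(
            c == chrom and start - min_gap_bp < e and s0 < end + min_gap_bp
            for c, s0, e in taken
        )
        if clash:
            continue
        taken.append((chrom, start, end))
        rows = np.concatenate(idx_lists[s: s + width])
        runs.append((chrom, start, end, rows))
    if len(runs) < n_runs:
        raise ValueError(
            f"could not place {n_runs} spike runs of {width} sites; "
            "genome too small or too crowded"
        )
    return runs


def _pick_target_windows(cfg, rng, truth) -> list[tuple]:
    """Designate the gene-set target windows spikes cluster into."""
    if cfg.n_target_windows == 0 or cfg.spike_cluster_frac == 0:
        return []
    windows: list[tuple] = []
    guard = 0
    while len(windows) < cfg.n_target_windows and guard < 1000:
        guard += 1
        chrom = f"chr{int(rng.integers(cfg.n_chrom)) + 1}"
        s = int(rng.integers(0, max(cfg.chrom_len - cfg.target_window_bp, 1)))
        e = s + cfg.target_window_bp
        if any(c == chrom and s < we and ws < e for c, ws, we in windows):
            continue
        windows.append((chrom, s, e))
    truth.target_windows = [
        {"chrom": c, "start": s, "end": e} for c, s, e in windows
    ]
    return windows


def _spike_dmrs(cfg, rng, sites, mu, case_mask, truth) -> None:
    if cfg.n_spiked_dmrs_per_context == 0 or cfg.dmr_delta == 0:
        return
    windows = _pick_target_windows(cfg, rng, truth)
    taken: list[tuple] = []
    for context in ("CG", "CAC"):
        units = _dyad_units(sites, context)
        if not units:
            continue
        n_total = cfg.n_spiked_dmrs_per_context
        n_clustered = int(round(cfg.spike_cluster_frac * n_total)) if windows else 0
        runs = _pick_runs(
            rng, units, n_clustered, cfg.dmr_width_sites, taken, windows=windows
        )
        runs += _pick_runs(
            rng, units, n_total - n_clustered, cfg.dmr_width_sites, taken
        )
        for j, (chrom, start, end, rows) in enumerate(runs):
            sign = 1 if j % 2 == 0 else -1
            if context == "CAC" and sign < 0:
                # a loss needs headroom: place hypo spikes on sites from the
                # methylated minority component (10-20% baseline)
                mu[rows, :] = rng.uniform(0.12, 0.18, size=rows.size)[:, None]
            mu[np.ix_(rows, np.flatnonzero(case_mask))] += sign * cfg.dmr_delta
            truth.true_dmrs.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "context": context,
                    "delta_sign": sign,
                }
            )


def _confound_regions(cfg, rng, sites, mu, meta, truth) -> None:
    if cfg.n_confounded_regions == 0:
        return
    taken = [(d["chrom"], d["start"], d["end"]) for d in truth.true_dmrs]
    units = _dyad_units(sites, "CG")
    runs = _pick_runs(
        rng, units, cfg.n_confounded_regions, cfg.dmr_width_sites, taken
    )
    age = meta["age"].to_numpy()
    centred = cfg.age_effect_slope * (age - age.mean())
    for chrom, start, end, rows in runs:
        mu[rows, :] += centred[None, :]
        truth.confounded_regions.append(
            {"chrom": chrom, "start": start, "end": end, "context": "CG"}
        )


# ---------------------------------------------------------------------------
# chromatin-state tracks


def make_state_tracks(cfg: SimConfig, genome: GenomeModel):
    """Draw per-sample 200-bp state tracks around a latent baseline map.

    Each sample's track equals its group's latent map with independent
    per-bin mislabelling at rate `state_noise_eps` (a mislabelled bin takes a
    uniformly random *different* state). Spiked segments carry a different
    latent state in the case group only.

    Returns (tracks, truth) where tracks is an
    :class:`epidiff.chromstate.StateTracks`.
    """
    from .chromstate import StateTracks

    rng = _rng(cfg.seed, "tracks")
    n_ref, n_case = cfg.n_tracks_per_group
    n = n_ref + n_case
    samples = [f"P{i + 1:02d}" for i in range(n)]
    groups = ["C"] * n_ref + ["ELA"] * n_case
    case_cols = np.arange(n_ref, n)

    truth = TruthSet()
    labels: dict[str, np.ndarray] = {}
    for chrom, size in genome.chrom_sizes.items():
        n_bins = size // cfg.bin_bp
        base = _segmented_baseline(cfg, rng, n_bins)
        case = base.copy()
        labels[chrom] = np.empty((n, n_bins), dtype=np.int16)
        # spiked group-switched segments, uniformly over chromosomes
        n_sp = cfg.n_spiked_transitions // cfg.n_chrom
        if chrom == list(genome.chrom_sizes)[-1]:
            n_sp = cfg.n_spiked_transitions - n_sp * (cfg.n_chrom - 1)
        placed = 0
        guard = 0
        occupied = np.zeros(n_bins, dtype=bool)
        while placed < n_sp and guard < 1000 * max(n_sp, 1):
            guard += 1
            w = cfg.spiked_transition_bins
            s = int(rng.integers(0, n_bins - w))
            # keep a one-bin margin so merged regions stay distinct
            if occupied[max(0, s - 1): s + w + 1].any():
                continue
            seg = base[s: s + w]
            if (seg != seg[0]).any():
                continue  # need a homogeneous baseline segment
            new = int(rng.integers(cfg.n_states))
            if new == seg[0]:
                continue
            case[s: s + w] = new
            occupied[s: s + w] = True
            truth.true_transitions.append(
                {
                    "chrom": chrom,
                    "start": s * cfg.bin_bp,
                    "end": (s + w) * cfg.bin_bp,
                    "state_from": int(seg[0]),
                    "state_to": new,
                }
            )
            placed += 1
        if placed < n_sp:
            raise ValueError("could not place spiked transition segments")

        for i in range(n):
            latent = case if i in case_cols else base
            track = latent.copy()
            if cfg.state_noise_eps > 0:
                flip = rng.random(n_bins) < cfg.state_noise_eps
                shift = rng.integers(1, cfg.n_states, size=int(flip.sum()))
                track[flip] = (track[flip] + shift) % cfg.n_states
            labels[chrom][i] = track

    tracks = StateTracks(
        samples=samples, groups=groups, bin_bp=cfg.bin_bp, labels=labels,
        n_states=cfg.n_states,
    )
    return tracks, truth


def _segmented_baseline(cfg, rng, n_bins) -> np.ndarray:
    out = np.empty(n_bins, dtype=np.int16)
    i = 0
    state = int(rng.integers(cfg.n_states))
    while i < n_bins:
        length = 1 + int(rng.geometric(1.0 / cfg.state_segment_mean_bins))
        nxt = int(rng.integers(cfg.n_states))
        out[i: i + length] = state
        i += length
        state = nxt
    return out


# ---------------------------------------------------------------------------
# ranked gene lists


def make_ranked_lists(cfg: SimConfig):
    """Two gene tables with signed metrics correlated at `ranked_list_corr`.

    The latent pair (zA, zB) is bivariate normal with the requested
    correlation; each table back-fills p = 10**(-|z|) and a log2 fold change
    whose sign matches z, so the signed metric -log10(p) * sign(lfc)
    recomputes to z exactly.
    """
    rng = _rng(cfg.seed, "lists")
    r = cfg.ranked_list_corr
    n = cfg.n_genes
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal(n)
    z = np.column_stack([z1, z2])
    genes = [f"G{i:04d}" for i in range(n)]

    def table(col):
        m = z[:, col]
        p = np.power(10.0, -np.abs(m))
        lfc = np.sign(m) * (0.1 + np.abs(m) / 2.0)
        lfc[m == 0] = 0.0
        df = pd.DataFrame({"gene": genes, "p": p, "lfc": lfc})
        return df

    return table(0), table(1)


# ---------------------------------------------------------------------------
# gene sets


def make_gene_sets(
    cfg: SimConfig,
    genome: GenomeModel,
    target_windows=None,
    n_background: int = 40,
    term_size: tuple[int, int] = (5, 30),
):
    """Flat gene-set collection with designed-enriched terms over spikes.

    One enriched term per target window, containing the genes whose
    regulatory domains intersect that window — i.e. the genes whose cis
    territory the clustered spikes fall into. Background terms sample genes
    uniformly. Windows covering no gene domain are skipped. Returns
    (gene_sets dict, enriched term ids).
    """
    from .enrichment import basal_plus_extension

    rng = _rng(cfg.seed, "genesets")
    genes = genome.genes
    if genes.empty:
        raise ValueError("genome has no genes")
    universe = list(genes["gene_id"])
    lo, hi = term_size
    if hi > len(universe):
        raise ValueError("term size exceeds gene universe")

    gene_sets: dict[str, list[str]] = {}
    enriched_ids: list[str] = []
    if target_windows:
        domains = basal_plus_extension(genes, genome.chrom_sizes)
        for i, w in enumerate(target_windows):
            c, s, e = w["chrom"], w["start"], w["end"]
            sub = domains[
                (domains["chrom"] == c)
                & (domains["ext_start"] < e)
                & (domains["ext_end"] > s)
            ]
            members = sorted(sub["gene_id"])
            if not members:
                continue
            tid = f"ENRICHED:{i:02d}"
            gene_sets[tid] = members
            enriched_ids.append(tid)
    for i in range(n_background):
        k = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=k, replace=False)
        gene_sets[f"BG:{i:03d}"] = sorted(members)
    return gene_sets, enriched_ids


# ---------------------------------------------------------------------------
# writers


def write_simulation(outdir, cfg: SimConfig, contexts=("CG", "CAC")) -> dict:
    """Run the full generator and write everything to `outdir`.

    Emits per-sample coverage TSVs (chrom, start, end, strand, context,
    n_meth, n_total), sample metadata, per-sample BED4 state tracks, a gene
    BED, a GMT gene-set collection, two ranked-list TSVs and a truth JSON.
    Returns the paths written, keyed by output class.
    """
    from .io import write_gmt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = make_genome(cfg)
    table, meta, truth = make_methylomes(cfg, genome, contexts=contexts)
    tracks, ttruth = make_state_tracks(cfg, genome)
    truth.true_transitions = ttruth.true_transitions
    la, lb = make_ranked_lists(cfg)
    n_genes = len(genome.genes)
    gene_sets, enriched = make_gene_sets(
        cfg, genome, target_windows=truth.target_windows,
        term_size=(min(5, n_genes), min(30, n_genes)),
    )
    truth.enriched_terms = enriched

    paths: dict[str, list[str]] = {"methylomes": [], "tracks": []}
    for i, s in enumerate(table.samples):
        df = table.sites.copy()
        df["start"] = df["pos"]
        df["end"] = df["pos"] + 1
        df["n_meth"] = table.meth[:, i]
        df["n_total"] = table.total[:, i]
        p = out / f"meth_{s}.tsv"
        df[["chrom", "start", "end", "strand", "context", "n_meth", "n_total"]
           ].to_csv(p, sep="\t", index=False)
        paths["methylomes"].append(str(p))
    meta.to_csv(out / "samples.tsv", sep="\t", index=False)

    for i, s in enumerate(tracks.samples):
        p = out / f"states_{s}.bed"
        with open(p, "w") as fh:
            for chrom, lab in tracks.labels.items():
                row = lab[i]
                edges = np.flatnonzero(np.diff(row)) + 1
                starts = np.concatenate([[0], edges])
                ends = np.concatenate([edges, [row.size]])
                for a, b in zip(starts, ends):
                    fh.write(
                        f"{chrom}\t{a * tracks.bin_bp}\t{b * tracks.bin_bp}"
                        f"\tS{row[a] + 1}\n"
                    )
        paths["tracks"].append(str(p))

    genome.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    write_gmt(gene_sets, out / "gene_sets.gmt")
    la.to_csv(out / "ranked_A.tsv", sep="\t", index=False)
    lb.to_csv(out / "ranked_B.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    paths.update(
        samples=str(out / "samples.tsv"),
        genes=str(out / "genes.tsv"),
        gene_sets=str(out / "gene_sets.gmt"),
        ranked=[str(out / "ranked_A.tsv"), str(out / "ranked_B.tsv")],
        truth=str(out / "truth.json"),
    )
    return paths
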