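"""Methylation-table operations against hand computations and brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epidiff.methylome import (
    MethylTable,
    build_table,
    classify_contexts,
    context_summary,
    filter_coverage,
    level_histogram,
    mask_sites,
    merge_cg,
    profile_over_intervals,
    read_calls,
    state_methylation,
)

from conftest import toy_table


# -- IO ----------------------------------------------------------------------

def test_read_calls_empty_file_warns(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("chrom\tstart\tend\tstrand\tcontext\tn_meth\tn_total\n")
    with pytest.warns(UserWarning, match="no records"):
        df = read_calls(p)
    assert df.empty


def test_read_calls_invalid_counts_name_the_line(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(
        "chrom\tstart\tend\tstrand\tcontext\tn_meth\tn_total\n"
        "chr1\t10\t11\t+\tCGA\t3\t10\n"
        "chr1\t20\t21\t+\tCGA\t12\t10\n"
    )
    with pytest.raises(ValueError, match="line 3"):
        read_calls(p)


def test_read_calls_unknown_dialect():
    with pytest.raises(ValueError, match="dialect"):
        read_calls("x.tsv", dialect="vcf")


def test_read_calls_bismark_coverage_dialect(tmp_path):
    p = tmp_path / "a.cov"
    p.write_text("chr1\t11\t11\t50.0\t5\t5\nchr1\t25\t25\t100.0\t4\t0\n")
    df = read_calls(p, dialect="bedGraph-cov")
    assert list(df["pos"]) == [10, 24]  # converted to 0-based
    assert list(df["n_total"]) == [10, 4]


# -- context classification --------------------------------------------------

def test_classify_plus_strand_cac():
    seqs = {"chr1": "TTCACTT"}
    rec = pd.DataFrame({"chrom": ["chr1"], "pos": [2], "strand": ["+"]})
    out = classify_contexts(seqs, rec)
    assert out["context"].iloc[0] == "CAC"


def test_classify_minus_strand_reverse_complement():
    # plus-strand triplet ending at pos is GTG -> minus-strand context CAC
    seqs = {"chr1": "AGTGA"}
    rec = pd.DataFrame({"chrom": ["chr1"], "pos": [3], "strand": ["-"]})
    out = classify_contexts(seqs, rec)
    assert out["context"].iloc[0] == "CAC"


def test_classify_non_cytosine_raises():
    seqs = {"chr1": "AAAA"}
    rec = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "strand": ["+"]})
    with pytest.raises(ValueError, match="not a cytosine"):
        classify_contexts(seqs, rec)


def test_classify_truncated_triplet_dropped():
    seqs = {"chr1": "ACG"}  # plus C at 1 has no pos+2 window -> keep (pos 1+2=3? no)
    rec = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "pos": [1, 2], "strand": ["+", "-"]}
    )
    out = classify_contexts(seqs, rec)
    # plus C at 1: triplet would need pos 3 -> dropped; minus C at 2 needs pos-2=0 -> kept
    assert len(out) == 1
    assert out["strand"].iloc[0] == "-"


def test_classify_all_triplets_yield_exactly_16_contexts():
    """A sequence containing all 64 triplets emits exactly 16 CNN labels."""
    from itertools import product

    seq = "".join("".join(t) for t in product("ACGT", repeat=3))
    plus = [i for i, b in enumerate(seq) if b == "C" and i + 2 < len(seq)]
    minus = [i for i, b in enumerate(seq) if b == "G" and i - 2 >= 0]
    rec = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": plus + minus,
            "strand": ["+"] * len(plus) + ["-"] * len(minus),
        }
    )
    out = classify_contexts({"chr1": seq}, rec)
    assert out["context"].nunique() == 16
    assert all(c.startswith("C") for c in out["context"].astype(str))


def test_classify_strand_symmetry():
    """Reverse-complementing the genome and flipping strands preserves contexts."""
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    comp = str.maketrans("ACGT", "TGCA")
    rc = seq.translate(comp)[::-1]
    n = len(seq)

    def all_contexts(s):
        plus = [i for i, b in enumerate(s) if b == "C" and i + 2 < n]
        minus = [i for i, b in enumerate(s) if b == "G" and i - 2 >= 0]
        rec = pd.DataFrame(
            {
                "chrom": "c",
                "pos": plus + minus,
                "strand": ["+"] * len(plus) + ["-"] * len(minus),
            }
        )
        return sorted(classify_contexts({"c": s}, rec)["context"].astype(str))

    assert all_contexts(seq) == all_contexts(rc)


# -- strand merging ----------------------------------------------------------

def test_merge_cg_sums_dyad_counts():
    t = toy_table(
        [
            ("chr1", 10, "+", "CGA", [5], [10]),
            ("chr1", 11, "-", "CGT", [3], [10]),
        ]
    )
    m = merge_cg(t)
    assert m.n_sites == 1
    assert m.sites["pos"].iloc[0] == 10
    assert m.meth[0, 0] == 8 and m.total[0, 0] == 20
    assert m.fraction()[0, 0] == pytest.approx(0.40)


def test_merge_cg_unpaired_minus_kept_at_dyad_position():
    t = toy_table([("chr1", 21, "-", "CGT", [4], [8])])
    m = merge_cg(t)
    assert m.sites["pos"].iloc[0] == 20
    assert m.total[0, 0] == 8


def test_merge_cg_non_cg_rows_pass_through():
    t = toy_table(
        [
            ("chr1", 5, "+", "CAC", [1], [4]),
            ("chr1", 10, "+", "CGA", [5], [10]),
        ]
    )
    m = merge_cg(t)
    assert set(m.sites["context"]) == {"CAC", "CGN"}


@given(st.integers(min_value=0, max_value=40), st.integers(min_value=0, max_value=40))
def test_merge_cg_conserves_total_counts(a, b):
    t = toy_table(
        [
            ("chr1", 10, "+", "CGA", [min(a, 40)], [40]),
            ("chr1", 11, "-", "CGT", [min(b, 40)], [40]),
            ("chr1", 30, "+", "CGC", [2], [7]),
        ]
    )
    m = merge_cg(t)
    assert m.total.sum() == t.total.sum()
    assert m.meth.sum() == t.meth.sum()


# -- filtering ---------------------------------------------------------------

def _meta(n_ref, n_case):
    rows = [(f"C{i}", "C", 30 + i, "M") for i in range(n_ref)]
    rows += [(f"E{i}", "ELA", 40 + i, "F") for i in range(n_case)]
    return pd.DataFrame(rows, columns=["sample", "group", "age", "sex"])


def test_filter_coverage_boundary_both_groups_required():
    """10 covered reference samples but only 9 covered case samples -> dropped."""
    n_ref, n_case = 12, 12
    meta = _meta(n_ref, n_case)
    total = np.array([[10] * n_ref + [10] * 9 + [0] * 3])
    meth = np.zeros_like(total)
    t = MethylTable(
        pd.DataFrame({"chrom": ["chr1"], "pos": [0], "strand": ["+"], "context": ["CGA"]}),
        meth, total, list(meta["sample"]),
    )
    assert filter_coverage(t, meta).n_sites == 0
    total2 = np.full((1, 24), 10)
    t2 = MethylTable(t.sites, np.zeros_like(total2), total2, list(meta["sample"]))
    assert filter_coverage(t2, meta).n_sites == 1


def test_filter_coverage_matches_bruteforce(small_methylomes):
    table, meta, _ = small_methylomes
    sub = table.take(np.arange(min(500, table.n_sites)))
    got = filter_coverage(sub, meta, min_cov=4, min_samples_per_group=5)
    ref_cols = [sub.samples.index(s) for s in meta[meta["group"] == "C"]["sample"]]
    case_cols = [sub.samples.index(s) for s in meta[meta["group"] == "ELA"]["sample"]]
    keep = []
    for i in range(sub.n_sites):
        ok_ref = sum(sub.total[i, c] >= 4 for c in ref_cols) >= 5
        ok_case = sum(sub.total[i, c] >= 4 for c in case_cols) >= 5
        keep.append(ok_ref and ok_case)
    assert got.n_sites == sum(keep)


def test_filter_coverage_monotone_in_min_cov(small_methylomes):
    table, meta, _ = small_methylomes
    sub = table.take(np.arange(min(1000, table.n_sites)))
    n_prev = sub.n_sites
    for cov in (2, 4, 6, 8):
        n = filter_coverage(sub, meta, min_cov=cov, min_samples_per_group=5).n_sites
        assert n <= n_prev
        n_prev = n


def test_filter_coverage_cohort_mean_preset():
    t = toy_table(
        [
            ("chr1", 0, "+", "CGA", [0, 0], [6, 6]),
            ("chr1", 5, "+", "CGA", [0, 0], [3, 4]),
        ]
    )
    out = filter_coverage(t, min_cov=5, min_samples_per_group=None)
    assert out.n_sites == 1


def test_mask_sites_identity_and_full_mask(small_methylomes):
    table, _, _ = small_methylomes
    sub = table.take(np.arange(200))
    assert mask_sites(sub).n_sites == 200
    assert mask_sites(sub, [("chr1", 0, 10**9)]).n_sites == 0


def test_mask_sites_matches_bruteforce(small_methylomes):
    table, _, _ = small_methylomes
    sub = table.take(np.arange(300))
    rng = np.random.default_rng(4)
    ivs = [("chr1", int(s), int(s) + 500) for s in rng.integers(0, 300_000, 5)]
    snps = [("chr1", int(p)) for p in sub.sites["pos"].iloc[::17]]
    got = mask_sites(sub, ivs, snps)
    keep = []
    snpset = set(snps)
    for _, r in sub.sites.iterrows():
        in_iv = any(r["chrom"] == c and s <= r["pos"] < e for c, s, e in ivs)
        keep.append(not in_iv and (r["chrom"], r["pos"]) not in snpset)
    assert got.n_sites == sum(keep)


# -- summaries ---------------------------------------------------------------

def test_context_summary_fully_methylated_is_100():
    t = toy_table(
        [
            ("chr1", 0, "+", "CAC", [5, 8], [5, 8]),
            ("chr1", 9, "+", "CGA", [3, 2], [3, 2]),
        ]
    )
    out = context_summary(t)
    assert np.allclose(out.to_numpy(), 100.0)


def test_context_summary_unweighted_mean_matches_loop(small_methylomes):
    table, _, _ = small_methylomes
    sub = table.take(np.arange(400))
    out = context_summary(sub, percent=False)
    frac = sub.fraction()
    ctx = sub.sites["context"].astype(str)
    for c in out.index:
        rows = np.flatnonzero((ctx == c).to_numpy())
        for j, s in enumerate(sub.samples):
            vals = [frac[i, j] for i in rows if not np.isnan(frac[i, j])]
            if vals:
                assert out.loc[c, s] == pytest.approx(np.mean(vals))


def test_context_summary_ignores_other_samples_when_subsetting(small_methylomes):
    table, _, _ = small_methylomes
    sub = table.take(np.arange(300))
    full = context_summary(sub)
    solo = context_summary(sub.subset_samples(sub.samples[:2]))
    pd.testing.assert_frame_equal(full[sub.samples[:2]], solo)


def test_level_histogram_all_zero_in_first_bin():
    t = toy_table([("chr1", i, "+", "CAC", [0], [10]) for i in range(5)])
    h = level_histogram(t, "CAC")
    assert h.iloc[0, 0] == 1.0
    assert h.iloc[1:, 0].sum() == 0.0


def test_level_histogram_sums_to_one(small_methylomes):
    table, _, _ = small_methylomes
    h = level_histogram(table.take(np.arange(500)))
    assert np.allclose(h.sum(axis=0), 1.0)


def test_level_histogram_empty_table():
    t = toy_table([("chr1", 0, "+", "CAC", [0], [1])])
    assert level_histogram(t.take(np.array([], dtype=int))).empty


def test_level_histogram_cac_minority_component_visible(small_methylomes):
    """The 10-20% CAC mixture component puts mass in the [10,20) bin."""
    table, _, _ = small_methylomes
    h = level_histogram(table.select_context("CAC"))
    assert h.loc["[10,20)"].mean() > h.loc["[30,40)"].mean()


def test_profile_constant_signal_is_flat():
    sites = [("chr1", p, "+", "CAC", [6], [10]) for p in range(0, 5000, 50)]
    t = toy_table(sites)
    ivs = pd.DataFrame({"chrom": ["chr1"], "start": [2000], "end": [3000]})
    prof = profile_over_intervals(t, ivs, flank_bp=1200, n_bins=4, n_flank_bins=3)
    assert np.allclose(prof.to_numpy(), 0.6)


def test_profile_single_interval_single_bin_equals_mean():
    t = toy_table(
        [
            ("chr1", 10, "+", "CAC", [2], [10]),
            ("chr1", 20, "+", "CAC", [8], [10]),
        ]
    )
    ivs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [30]})
    prof = profile_over_intervals(t, ivs, flank_bp=10, n_bins=1, n_flank_bins=1)
    assert prof.iloc[1, 0] == pytest.approx(0.5)


def test_profile_minus_strand_reversed():
    t = toy_table(
        [
            ("chr1", 100, "+", "CAC", [0], [10]),
            ("chr1", 900, "+", "CAC", [10], [10]),
        ]
    )
    plus = pd.DataFrame(
        {"chrom": ["chr1"], "start": [0], "end": [1000], "strand": ["+"]}
    )
    minus = plus.assign(strand="-")
    kw = dict(flank_bp=100, n_bins=4, n_flank_bins=1)
    p1 = profile_over_intervals(t, plus, **kw).iloc[:, 0].dropna()
    p2 = profile_over_intervals(t, minus, **kw).iloc[:, 0].dropna()
    assert list(p1) == list(p2[::-1])


def test_state_methylation_single_state_equals_genome_mean(small_methylomes):
    from epidiff.chromstate import ConsensusMap

    table, _, _ = small_methylomes
    sub = table.take(np.arange(400))
    n_bins = 300_000 // 200
    cmap = ConsensusMap(
        200, {"chr1": np.zeros(n_bins, dtype=np.int16)},
        {"chr1": np.full(n_bins, 5)}, 10,
    )
    out = state_methylation(sub, cmap)
    frac = sub.fraction()
    expected = np.nanmean(frac, axis=0)
    assert np.allclose(out.loc[0].to_numpy(), expected, equal_nan=True)


def test_state_methylation_matches_bruteforce_on_toy():
    from epidiff.chromstate import ConsensusMap

    t = toy_table(
        [
            ("chr1", 50, "+", "CAC", [1], [10]),    # bin 0 -> state 2
            ("chr1", 250, "+", "CAC", [5], [10]),   # bin 1 -> state 3
            ("chr1", 450, "+", "CAC", [9], [10]),   # bin 2 -> ambiguous
        ]
    )
    lab = np.array([2, 3, -1], dtype=np.int16)
    cmap = ConsensusMap(200, {"chr1": lab}, {"chr1": np.full(3, 9)}, 10)
    out = state_methylation(t, cmap)
    assert out.loc[2, "s0"] == pytest.approx(0.1)
    assert out.loc[3, "s0"] == pytest.approx(0.5)
    assert -1 not in out.index  # ambiguous bins excluded
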