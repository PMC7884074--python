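"""The 1 kb-bin ChIP procedure: extension, binning, exclusion, ratios,
differential calls, bin classes, cluster tests, anchored profiles."""

import numpy as np
import pandas as pd
import pytest

from pirna_dimorph import chip as ch
from conftest import make_loci, make_reads

SIZES = {"c": 10_000}


def frags(rows):
    """rows: (chrom, start, end); unit weight fragments."""
    return pd.DataFrame([(c, s, e, "+", 1.0, 1) for c, s, e in rows],
                        columns=["chrom", "start", "end", "strand",
                                 "weight", "n_hits"])


# --------------------------------------------------------------------------
# read extension
# --------------------------------------------------------------------------

def test_extend_read_both_strands_and_clipping():
    reads = make_reads([
        ("c", 100, 150, "+", 1.0, 1),
        ("c", 450, 500, "-", 1.0, 1),
        ("c", 50, 100, "-", 1.0, 1),
        ("c", 9950, 9990, "+", 1.0, 1),
    ])
    ext = ch.extend_reads(reads, 200, SIZES)
    assert (ext.loc[0, "start"], ext.loc[0, "end"]) == (100, 300)
    assert (ext.loc[1, "start"], ext.loc[1, "end"]) == (300, 500)
    assert (ext.loc[2, "start"], ext.loc[2, "end"]) == (0, 100)   # left clip
    assert (ext.loc[3, "start"], ext.loc[3, "end"]) == (9950, 10_000)


def test_overlong_read_left_unextended_with_warning():
    reads = make_reads([("c", 100, 400, "+", 1.0, 1)])
    with pytest.warns(UserWarning, match="unextended"):
        ext = ch.extend_reads(reads, 200, SIZES)
    assert (ext.loc[0, "start"], ext.loc[0, "end"]) == (100, 400)


# --------------------------------------------------------------------------
# bin coverage
# --------------------------------------------------------------------------

def test_fragment_inside_one_bin():
    bins = ch.make_bins(SIZES, 1000)
    raw = ch.bin_coverage(frags([("c", 2100, 2300)]), bins, 1000)
    assert raw[2] == pytest.approx(1.0)
    assert raw.sum() == pytest.approx(1.0)


def test_fragment_split_proportionally_across_bins():
    bins = ch.make_bins(SIZES, 1000)
    raw = ch.bin_coverage(frags([("c", 1850, 2050)]), bins, 1000)
    assert raw[1] == pytest.approx(0.75)
    assert raw[2] == pytest.approx(0.25)


def test_count_in_every_bin_mode():
    bins = ch.make_bins(SIZES, 1000)
    raw = ch.bin_coverage(frags([("c", 1850, 2050)]), bins, 1000, split=False)
    assert raw[1] == raw[2] == 1.0


def test_weight_conservation_with_clipped_fragments():
    rng = np.random.default_rng(1)
    starts = rng.integers(-100, 10_050, size=2000)
    rows = [("c", max(0, s), min(10_000, s + 200)) for s in starts
            if min(10_000, s + 200) - max(0, s) > 0]
    bins = ch.make_bins(SIZES, 1000)
    raw = ch.bin_coverage(frags(rows), bins, 1000)
    assert raw.sum() == pytest.approx(len(rows), rel=1e-9)


def test_binning_independent_of_read_order():
    rng = np.random.default_rng(2)
    rows = [("c", int(s), int(s) + 200) for s in rng.integers(0, 9800, 500)]
    bins = ch.make_bins(SIZES, 1000)
    a = ch.bin_coverage(frags(rows), bins, 1000)
    b = ch.bin_coverage(frags(rows[::-1]), bins, 1000)
    assert np.allclose(a, b)


def test_per_million_normalization_excludes_chroms():
    sizes = {"c": 10_000, "MtDNA": 1000}
    bins = ch.make_bins(sizes, 1000)
    f = frags([("c", 0, 200)] * 3 + [("MtDNA", 0, 200)])
    raw = ch.bin_coverage(f, bins, 1000)
    cpm = ch.normalize_coverage(raw, f, bins, exclude_chroms=["MtDNA"])
    # depth = 3 (MtDNA excluded); bin 'c':0 holds 3 fragments
    c0 = bins[(bins.chrom == "c") & (bins.start == 0)].index[0]
    assert cpm[c0] == pytest.approx(3 * 1e6 / 3)


def test_zero_fragments_rejected():
    bins = ch.make_bins(SIZES, 1000)
    with pytest.raises(ValueError):
        ch.bin_coverage(frags([]), bins, 1000)


# --------------------------------------------------------------------------
# exclusion filter
# --------------------------------------------------------------------------

def _toy_bins(n=5, size=1000):
    return pd.DataFrame({"chrom": "c", "start": np.arange(n) * size,
                         "end": (np.arange(n) + 1) * size})


def test_exclusion_median_and_strict_less_rule():
    bins = _toy_bins(5)
    loci = make_loci([])  # all bins piRNA-depleted
    input_cpm = pd.Series([0.0, 1.0, 2.0, 3.0, 100.0])
    ip_cpm = pd.Series([1.9, 2.0, 2.1, 5.0, 0.0])
    excluded, t = ch.exclusion_filter(ip_cpm, input_cpm, bins, loci, "c", 1000)
    assert t == 2.0
    assert list(excluded) == [True, False, False, False, True]


def test_exclusion_zero_input_excludes_nothing():
    bins = _toy_bins(4)
    excluded, t = ch.exclusion_filter(
        pd.Series([0.0] * 4), pd.Series([0.0] * 4), bins, make_loci([]),
        "c", 1000)
    assert t == 0.0 and not excluded.any()


def test_exclusion_requires_depleted_bins():
    bins = _toy_bins(2)
    loci = make_loci([("L0", "c", 100, 121, "+", "male"),
                      ("L1", "c", 1100, 1121, "+", "male")])
    with pytest.raises(ValueError, match="depleted"):
        ch.exclusion_filter(pd.Series([1.0, 1.0]), pd.Series([1.0, 1.0]),
                            bins, loci, "c", 1000)


def test_exclusion_matches_bruteforce_median():
    rng = np.random.default_rng(5)
    bins = _toy_bins(50)
    loci = make_loci([
        (f"L{i}", "c", int(p), int(p) + 21, "+", "male")
        for i, p in enumerate(rng.integers(0, 49_000, 12))
    ])
    ip = pd.Series(rng.gamma(2, 50, size=50))
    inp = pd.Series(rng.gamma(2, 50, size=50))
    excluded, t = ch.exclusion_filter(ip, inp, bins, loci, "c", 1000)
    has_p5 = np.zeros(50, dtype=bool)
    for _, l in loci.iterrows():
        has_p5[l.start // 1000] = True
    ref = sorted(inp[~has_p5])
    n = len(ref)
    t_ref = (ref[n // 2] if n % 2 else (ref[n // 2 - 1] + ref[n // 2]) / 2)
    assert t == pytest.approx(t_ref)
    assert list(excluded) == list(ip < t_ref)


# --------------------------------------------------------------------------
# ratios and differential bins
# --------------------------------------------------------------------------

def test_bin_ratio_pseudocount_contract():
    ip = pd.Series([10.0, 0.0, 99.0])
    inp = pd.Series([10.0, 0.0, 0.0])
    r = ch.bin_ratio(ip, inp, pseudocount=1.0)
    assert list(r) == [1.0, 1.0, 100.0]


def test_differential_bin_fold_threshold_strict():
    case = pd.Series([4.0, 1.9])
    ctrl = pd.Series([1.0, 1.0])
    called = ch.call_differential_bins(case, ctrl, fold=2.0)
    assert list(called) == [True, False]


def test_differential_direction_duality():
    rng = np.random.default_rng(6)
    case = pd.Series(rng.gamma(2, 1, 100))
    ctrl = pd.Series(rng.gamma(2, 1, 100))
    eligible = pd.Series(rng.random(100) < 0.8)
    enr = ch.call_differential_bins(case, ctrl, 2.0, "enriched", eligible)
    dep = ch.call_differential_bins(ctrl, case, 2.0, "depleted", eligible)
    assert (enr == dep).all()


def test_differential_rejects_mismatched_bins():
    with pytest.raises(ValueError, match="bin set"):
        ch.call_differential_bins(pd.Series([1.0], index=[0]),
                                  pd.Series([1.0], index=[1]))


# --------------------------------------------------------------------------
# bin classification
# --------------------------------------------------------------------------

def test_classify_bins_by_five_prime_content():
    bins = _toy_bins(4)
    loci = make_loci([
        ("m1", "c", 100, 121, "+", "male"),
        ("m2", "c", 300, 321, "+", "male"),
        ("m3", "c", 600, 621, "+", "male"),
        ("f1", "c", 1100, 1121, "+", "female"),
        ("m4", "c", 1500, 1521, "+", "male"),
        ("n1", "c", 2200, 2221, "+", "NE"),
        # 5' nt on the minus strand lies at end-1 = 3010 -> bin 3
        ("f2", "c", 2990, 3011, "-", "female"),
    ])
    content = ch.classify_bins(bins, loci, 1000)
    assert list(content) == ["all_male", "mixed", "all_NE", "all_female"]


def test_locus_spanning_boundary_counts_in_five_prime_bin():
    bins = _toy_bins(2)
    # plus-strand locus straddling the boundary: 5' nt at 990 -> bin 0 only
    loci = make_loci([("x", "c", 990, 1011, "+", "male")])
    counts = ch.pirna_5p_bin_counts(bins, loci, 1000)
    assert counts.loc[0, "male"] == 1 and counts.loc[1, "male"] == 0


# --------------------------------------------------------------------------
# cluster test
# --------------------------------------------------------------------------

def test_cluster_wilcoxon_single_equal_bins():
    from pirna_dimorph.intervals import GenomicInterval
    bins = _toy_bins(2)
    ratio = pd.Series([1.0, 1.0])
    res = ch.cluster_wilcoxon(ratio, bins, [GenomicInterval("c", 0, 1000)],
                              "c")
    assert res["p"] == 1.0
    assert res["n_inside"] == res["n_outside"] == 1


def test_cluster_wilcoxon_empty_group_rejected():
    from pirna_dimorph.intervals import GenomicInterval
    bins = _toy_bins(2)
    with pytest.raises(ValueError, match="empty group"):
        ch.cluster_wilcoxon(pd.Series([1.0, 2.0]), bins,
                            [GenomicInterval("c", 0, 2000)], "c")


# --------------------------------------------------------------------------
# anchored profiles
# --------------------------------------------------------------------------

def test_constant_signal_gives_flat_profile_zero_se():
    bins = ch.make_bins(SIZES, 50)
    track = pd.Series(3.0, index=bins.index)
    anchors = make_loci([("a", "c", 2000, 2021, "+", "male"),
                         ("b", "c", 5000, 5021, "+", "male")])
    profile, heatmap = ch.anchored_profile(track, bins, 50, anchors,
                                           flank=500, profile_bin=50)
    assert np.allclose(profile["mean"], 3.0)
    assert np.allclose(profile["se"], 0.0)
    assert heatmap.shape == (2, 20)


def test_minus_strand_upstream_appears_left():
    bins = ch.make_bins(SIZES, 50)
    track = pd.Series(0.0, index=bins.index)
    # minus-strand anchor at 5' = 4020; genomic upstream = to the right
    track[(4100 // 50)] = 10.0  # genomic [4100, 4150) = positions -130..-81
    anchors = make_loci([("m", "c", 4000, 4021, "-", "male")])
    profile, _ = ch.anchored_profile(track, bins, 50, anchors,
                                     flank=500, profile_bin=50)
    peak_pos = profile.loc[profile["mean"].idxmax(), "position"]
    assert peak_pos < 0
    assert profile["mean"][profile["position"] == peak_pos].iloc[0] > 0


def test_off_chromosome_anchor_dropped_with_warning():
    bins = ch.make_bins(SIZES, 50)
    track = pd.Series(1.0, index=bins.index)
    anchors = make_loci([("edge", "c", 100, 121, "+", "male"),
                         ("ok", "c", 5000, 5021, "+", "male")])
    with pytest.warns(UserWarning, match="dropped"):
        profile, heatmap = ch.anchored_profile(track, bins, 50, anchors,
                                               flank=500, profile_bin=50)
    assert len(heatmap) == 1


def test_heatmap_rows_sorted_by_descending_mean():
    bins = ch.make_bins(SIZES, 50)
    track = pd.Series(0.0, index=bins.index)
    track[(3000 // 50)] = 5.0
    anchors = make_loci([("lo", "c", 6000, 6021, "+", "male"),
                         ("hi", "c", 3000, 3021, "+", "male")])
    _, heatmap = ch.anchored_profile(track, bins, 50, anchors,
                                     flank=500, profile_bin=50)
    assert list(heatmap.index) == ["hi", "lo"]
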