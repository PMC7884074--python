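"""Read filtering, counting modes, normalization, the NB Wald test, and
sex classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pirna_dimorph import smallrna as sr
from pirna_dimorph.config import Config
from conftest import make_loci, make_reads


# --------------------------------------------------------------------------
# filtering and QC
# --------------------------------------------------------------------------

def test_filter_by_length_keeps_published_window():
    reads = make_reads([("c", 0, 0 + l, "+", 1.0, 1) for l in (14, 15, 30, 31)])
    kept = sr.filter_by_length(reads, 15, 30)
    assert list(kept["end"] - kept["start"]) == [15, 30]


def test_filter_empty_and_degenerate_window():
    empty = make_reads([])
    assert len(sr.filter_by_length(empty, 15, 30)) == 0
    reads = make_reads([("c", 0, 21, "+", 1.0, 1), ("c", 0, 22, "+", 1.0, 1)])
    kept = sr.filter_by_length(reads, 21, 21)
    assert list(kept["end"] - kept["start"]) == [21]
    with pytest.raises(ValueError):
        sr.filter_by_length(reads, 30, 15)


def test_is_21u_on_taqman_probe_sequences():
    assert sr.is_21u("TAAAGGCAGAATTTTATCAAC")       # 21 nt, 5' U
    assert not sr.is_21u("GTAGGGTCGTCTCTTGAGAGC")   # 5' G
    assert not sr.is_21u("T" * 20)                  # wrong length
    with pytest.raises(ValueError):
        sr.is_21u("TAAAGGCAGAATTTTATCAAN")


def test_length_firstnt_table_weights_and_other_row():
    reads = make_reads([
        ("c", 0, 21, "+", 1.0, 1),
        ("c", 0, 21, "+", 0.5, 2),
        ("c", 100, 121, "+", 0.5, 2),
        ("c", 0, 40, "+", 1.0, 1),
    ])
    reads["first_nt"] = ["T", "T", "T", "A"]
    table = sr.length_firstnt_table(reads)
    assert table.at["21", "T"] == pytest.approx(2.0)  # 1 + 0.5 + 0.5
    assert table.at["other", "A"] == pytest.approx(1.0)
    assert table.to_numpy().sum() == pytest.approx(reads["weight"].sum())


def test_length_firstnt_single_read():
    reads = make_reads([("c", 0, 21, "+", 1.0, 1)])
    reads["first_nt"] = ["T"]
    table = sr.length_firstnt_table(reads)
    assert table.at["21", "T"] == 1.0
    assert table.to_numpy().sum() == 1.0


# --------------------------------------------------------------------------
# counting
# --------------------------------------------------------------------------

LOCI = make_loci([
    ("L1", "c", 100, 121, "+", "unassigned"),
    ("L2", "c", 500, 521, "+", "unassigned"),
])


def test_unique_read_counts_once_in_both_modes():
    reads = make_reads([("c", 100, 121, "+", 1.0, 1)])
    for mode in ("overlap_all", "proportional"):
        counts, unassigned = sr.count_over_loci(reads, LOCI, mode=mode)
        assert counts["L1"] == 1.0 and counts["L2"] == 0.0
        assert unassigned == 0.0


def test_two_hit_read_full_vs_proportional():
    # one read, two genomic hits, each on a distinct locus
    reads = make_reads([
        ("c", 100, 121, "+", 0.5, 2),
        ("c", 500, 521, "+", 0.5, 2),
    ])
    counts, _ = sr.count_over_loci(reads, LOCI, mode="overlap_all")
    assert counts.sum() == 2.0  # both loci +1
    counts, _ = sr.count_over_loci(reads, LOCI, mode="proportional")
    assert counts["L1"] == counts["L2"] == pytest.approx(0.5)


def test_read_over_two_overlapping_loci_splits():
    loci = make_loci([
        ("A", "c", 100, 121, "+", "unassigned"),
        ("B", "c", 110, 131, "+", "unassigned"),
    ])
    reads = make_reads([("c", 108, 129, "+", 1.0, 1)])
    counts, _ = sr.count_over_loci(reads, loci, mode="overlap_all")
    assert counts["A"] == counts["B"] == 1.0
    counts, _ = sr.count_over_loci(reads, loci, mode="proportional")
    assert counts["A"] == counts["B"] == pytest.approx(0.5)


def test_antisense_overlap_excluded_unless_requested():
    reads = make_reads([("c", 100, 121, "-", 1.0, 1)])
    counts, unassigned = sr.count_over_loci(reads, LOCI)
    assert counts.sum() == 0.0 and unassigned == 1.0
    counts, _ = sr.count_over_loci(reads, LOCI, ignore_strand=True)
    assert counts["L1"] == 1.0


def test_unknown_mode_rejected():
    with pytest.raises(ValueError):
        sr.count_over_loci(make_reads([]), LOCI, mode="bogus")


@st.composite
def read_locus_layout(draw):
    n_loci = draw(st.integers(1, 4))
    loci = []
    for i in range(n_loci):
        start = draw(st.integers(0, 300))
        loci.append((f"L{i}", "c", start, start + draw(st.integers(5, 40)),
                     draw(st.sampled_from("+-")), "unassigned"))
    n_reads = draw(st.integers(1, 12))
    reads = []
    for i in range(n_reads):
        n_hits = draw(st.integers(1, 3))
        for _ in range(n_hits):
            start = draw(st.integers(0, 340))
            reads.append(("c", start, start + draw(st.integers(5, 30)),
                          draw(st.sampled_from("+-")), 1.0 / n_hits, n_hits))
    return make_loci(loci), make_reads(reads), n_reads


@given(read_locus_layout())
@settings(max_examples=150, deadline=None)
def test_proportional_conserves_weight_and_overlap_all_dominates(layout):
    loci, reads, n_reads = layout
    prop, unassigned = sr.count_over_loci(reads, loci, mode="proportional")
    assert prop.sum() + unassigned == pytest.approx(n_reads)
    full, _ = sr.count_over_loci(reads, loci, mode="overlap_all")
    assert (full >= prop - 1e-9).all()


# --------------------------------------------------------------------------
# size factors
# --------------------------------------------------------------------------

def test_size_factors_doubled_sample():
    counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
    s = sr.size_factors(counts)
    assert s["s1"] == pytest.approx(1 / np.sqrt(2))
    assert s["s2"] == pytest.approx(np.sqrt(2))


def test_size_factors_identical_samples_are_one():
    counts = pd.DataFrame({"s1": [10, 20], "s2": [10, 20]})
    assert np.allclose(sr.size_factors(counts), 1.0)


def test_size_factors_scaling_equivariance():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.poisson(100, size=(50, 3)) + 1,
                          columns=list("abc"))
    s = sr.size_factors(counts)
    scaled = counts.copy()
    scaled["b"] *= 3
    s2 = sr.size_factors(scaled)
    assert s2["b"] / s["b"] == pytest.approx(3 * s2["a"] / s["a"], rel=1e-9)


def test_size_factors_need_common_nonzero_feature():
    counts = pd.DataFrame({"s1": [5, 0], "s2": [0, 7]})
    with pytest.raises(ValueError, match="pseudocount"):
        sr.size_factors(counts)


# --------------------------------------------------------------------------
# NB Wald test and classification
# --------------------------------------------------------------------------

GROUPS = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


def test_identical_groups_give_zero_lfc_p_one():
    counts = pd.DataFrame({
        "a1": [100, 50], "a2": [120, 60], "b1": [100, 50], "b2": [120, 60],
    }, index=["f1", "f2"])
    de = sr.nb_wald_test(counts, GROUPS, levels=("A", "B"))
    assert np.allclose(de["log2FC"], 0.0)
    assert np.allclose(de["p"], 1.0)
    assert (de["q"] >= de["p"] - 1e-12).all()


def test_missing_group_rejected():
    counts = pd.DataFrame({"a1": [1], "a2": [2]})
    with pytest.raises(ValueError, match="per group"):
        sr.nb_wald_test(counts, GROUPS, levels=("A", "B"))


def test_all_zero_features_reported_untestable():
    counts = pd.DataFrame({
        "a1": [100, 0], "a2": [120, 0], "b1": [300, 0], "b2": [310, 0],
    }, index=["f1", "f2"])
    de = sr.nb_wald_test(counts, GROUPS, levels=("A", "B"))
    assert de.loc["f2", "call"] == "NE"
    assert np.isnan(de.loc["f2", "p"])


def test_classification_thresholds_inclusive():
    de = pd.DataFrame({
        "log2FC": [0.30, 0.26, -1.0, -0.26, 0.4],
        "q": [0.01, 0.05, 0.20, 0.05, 0.051],
    }, index=list("abcde"))
    cls = sr.classify_pirnas(de)
    assert cls["a"] == "male"
    assert cls["b"] == "male"        # boundary values are inclusive
    assert cls["c"] == "NE"          # fails FDR
    assert cls["d"] == "female"
    assert cls["e"] == "NE"          # q just over threshold


def test_classify_requires_q():
    with pytest.raises(ValueError, match="q"):
        sr.classify_pirnas(pd.DataFrame({"log2FC": [1.0]}))


def test_classification_antisymmetric_under_label_swap():
    rng = np.random.default_rng(4)
    groups = pd.Series({f"s{i}": ("A" if i < 3 else "B") for i in range(6)})
    counts = pd.DataFrame(
        rng.poisson(
            np.column_stack([np.full((40, 3), 100), np.full((40, 3), 250)])),
        index=[f"f{i}" for i in range(40)],
        columns=[f"s{i}" for i in range(6)])
    de_ab = sr.nb_wald_test(counts, groups, levels=("A", "B"))
    de_ba = sr.nb_wald_test(counts, groups, levels=("B", "A"))
    cls_ab = sr.classify_pirnas(de_ab)
    cls_ba = sr.classify_pirnas(de_ba)
    swap = {"male": "female", "female": "male", "NE": "NE"}
    assert (cls_ab.map(swap) == cls_ba).all()
    assert np.allclose(de_ab["log2FC"], -de_ba["log2FC"], atol=1e-9)


def test_set_overlap_counts_and_fraction():
    a = pd.Series({"a": "male", "b": "male", "c": "male", "d": "NE"})
    b = pd.Series({"b": "male", "c": "male", "d": "male", "e": "female"})
    table = sr.set_overlap(a, b, classes=("male",))
    row = table.loc["male"]
    assert row["intersection"] == 2
    assert row["fraction_of_A"] == pytest.approx(2 / 3)
    same = sr.set_overlap(a, a, classes=("male",)).loc["male"]
    assert same["fraction_of_A"] == 1.0
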