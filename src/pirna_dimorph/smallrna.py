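"""Small RNA-seq analysis: from aligned reads to sex-classified piRNAs.

The workflow mirrors the two-condition (spermatogenesis vs oogenesis) design:
length filtering (15-30 nt), QC length x 5'-nt tables, locus counting in two
multi-mapper modes, median-of-ratios normalization, a self-contained
negative-binomial Wald test, threshold classification (|log2FC| >= 0.26,
BH FDR <= 0.05), and set-overlap reporting.

Counting is sense-strand only by default: piRNAs are stranded transcription
units, and the 22G-like antisense background must not leak into locus counts.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .config import Config
from .stats import bh_adjust

log = logging.getLogger(__name__)

LN2 = np.log(2.0)
COUNT_MODES = ("overlap_all", "proportional")


def filter_by_length(reads: pd.DataFrame, min_len: int,
                     max_len: int) -> pd.DataFrame:
    """Keep reads whose length lies in [min_len, max_len], order preserved."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    lengths = reads["end"] - reads["start"]
    keep = (lengths >= min_len) & (lengths <= max_len)
    removed = int((~keep).sum())
    if removed:
        log.info("filter_by_length: removed %d of %d reads", removed, len(reads))
    return reads[keep]


def is_21u(seq: str) -> bool:
    """True iff the read is a 21U-RNA candidate: 21 nt with a 5' U
    (T in DNA representation)."""
    if set(seq.upper()) - set("ACGT"):
        raise ValueError(f"non-ACGT character in sequence {seq!r}")
    return len(seq) == 21 and seq[0].upper() == "T"


def length_firstnt_table(reads: pd.DataFrame, min_len: int = 15,
                         max_len: int = 30) -> pd.DataFrame:
    """Summed read weight per (length, 5' nucleotide); the QC table used to
    verify the presence of 21U- and 22G-RNA species.

    Lengths outside [min_len, max_len] are collected in an ``other`` row.
    """
    if "first_nt" not in reads.columns:
        raise ValueError("reads must carry sequences (first_nt column)")
    lengths = (reads["end"] - reads["start"]).astype(int)
    index = [str(l) for l in range(min_len, max_len + 1)] + ["other"]
    table = pd.DataFrame(0.0, index=index, columns=list("ACGT"))
    in_range = (lengths >= min_len) & (lengths <= max_len)
    if (~in_range).any():
        log.warning("length_firstnt_table: %d reads outside [%d, %d] counted "
                    "as 'other'", int((~in_range).sum()), min_len, max_len)
    row = np.where(in_range, lengths.astype(str), "other")
    grouped = (
        pd.DataFrame({"row": row, "nt": reads["first_nt"],
                      "w": reads["weight"]})
        .groupby(["row", "nt"])["w"].sum()
    )
    for (r, nt), w in grouped.items():
        if nt in table.columns:
            table.at[r, nt] += w
    return table


# ---------------------------------------------------------------------------
# locus counting
# ---------------------------------------------------------------------------

def _sorted_nonoverlapping(starts: np.ndarray, ends: np.ndarray) -> bool:
    return bool(np.all(starts[1:] >= ends[:-1]))


def _count_group_fast(r_start, r_end, r_weight, l_start, l_end, l_idx,
                      counts, mode, min_overlap):
    """Vectorized counting against sorted, non-overlapping loci."""
    j_lo = np.searchsorted(l_end, r_start, side="right")
    j_hi = np.searchsorted(l_start, r_end, side="left")
    ncand = np.maximum(j_hi - j_lo, 0)
    max_c = int(ncand.max()) if len(ncand) else 0
    valid_per_read = np.zeros(len(r_start), dtype=np.int64)
    hits = []  # (read row positions, locus positions) per candidate offset
    for o in range(max_c):
        m = ncand > o
        j = j_lo[m] + o
        ov = (np.minimum(l_end[j], r_end[m])
              - np.maximum(l_start[j], r_start[m]))
        ok = ov >= min_overlap
        rows = np.flatnonzero(m)[ok]
        hits.append((rows, l_idx[j[ok]]))
        valid_per_read[rows] += 1
    for rows, loci_pos in hits:
        if mode == "overlap_all":
            np.add.at(counts, loci_pos, 1.0)
        else:
            np.add.at(counts, loci_pos,
                      r_weight[rows] / valid_per_read[rows])
    unassigned = float(r_weight[valid_per_read == 0].sum())
    return unassigned


def _count_group_tree(r_start, r_end, r_weight, l_start, l_end, l_idx,
                      counts, mode, min_overlap):
    """General counting (loci may overlap) via an interval tree."""
    tree = IntervalTree()
    for s, e, i in zip(l_start, l_end, l_idx):
        tree.addi(int(s), int(e), int(i))
    unassigned = 0.0
    for rs, re, w in zip(r_start, r_end, r_weight):
        matched = [
            iv.data for iv in tree.overlap(int(rs), int(re))
            if min(iv.end, re) - max(iv.begin, rs) >= min_overlap
        ]
        if not matched:
            unassigned += w
            continue
        if mode == "overlap_all":
            for i in matched:
                counts[i] += 1.0
        else:
            share = w / len(matched)
            for i in matched:
                counts[i] += share
    return unassigned


def count_over_loci(
    reads: pd.DataFrame,
    loci: pd.DataFrame,
    mode: str = "proportional",
    min_overlap: int = 1,
    ignore_strand: bool = False,
) -> Tuple[pd.Series, float]:
    """Assign read (hits) to loci; returns ``(counts, unassigned_weight)``.

    ``overlap_all``: every sense-strand overlap of >= ``min_overlap`` bp
    between a read hit and a locus adds the full read count 1 (a multi-hit or
    multi-locus read can contribute more than 1 in total) -- the behaviour of
    feature counting with overlapping and multi-mapping reads admitted.

    ``proportional``: each read carries total weight 1, split as
    ``1/n_hits`` per hit; a hit overlapping several loci splits its weight
    equally among them, so total assigned weight + unassigned weight equals
    the number of reads.
    """
    if mode not in COUNT_MODES:
        raise ValueError(f"unknown counting mode {mode!r}")
    if ((loci["end"] - loci["start"]) <= 0).any():
        raise ValueError("degenerate locus interval")
    counts = np.zeros(len(loci), dtype=float)
    unassigned = 0.0
    group_cols = ["chrom"] if ignore_strand else ["chrom", "strand"]
    loci_groups = dict(tuple(loci.reset_index(drop=True).groupby(group_cols)))
    for key, rgrp in reads.groupby(group_cols):
        lgrp = loci_groups.get(key)
        if lgrp is None:
            unassigned += float(rgrp["weight"].sum())
            continue
        lgrp = lgrp.sort_values("start")
        l_start = lgrp["start"].to_numpy()
        l_end = lgrp["end"].to_numpy()
        l_idx = lgrp.index.to_numpy()
        args = (rgrp["start"].to_numpy(), rgrp["end"].to_numpy(),
                rgrp["weight"].to_numpy(), l_start, l_end, l_idx,
                counts, mode, min_overlap)
        if _sorted_nonoverlapping(l_start, l_end):
            unassigned += _count_group_fast(*args)
        else:
            unassigned += _count_group_tree(*args)
    return pd.Series(counts, index=loci["id"].to_numpy(), name="count"), unassigned


def count_matrix(
    reads_by_sample: Mapping[str, pd.DataFrame],
    loci: pd.DataFrame,
    mode: str = "proportional",
    min_overlap: int = 1,
    ignore_strand: bool = False,
) -> pd.DataFrame:
    """Features x samples count matrix."""
    cols = {}
    for sid, reads in reads_by_sample.items():
        cols[sid], _ = count_over_loci(reads, loci, mode=mode,
                                       min_overlap=min_overlap,
                                       ignore_strand=ignore_strand)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# normalization and differential expression
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For features with nonzero counts in every sample,
    ``s_j = median_i(c_ij / geometric_mean_i)``; normalized counts are
    ``c_ij / s_j``.
    """
    c = counts.to_numpy(dtype=float)
    usable = (c > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; add a pseudocount "
            "or use a spike-in/normalizer feature"
        )
    cu = c[usable]
    log_geomean = np.mean(np.log(cu), axis=1)
    ratios = np.log(cu) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def pooled_dispersion(norm: np.ndarray, group_idx: Sequence[np.ndarray],
                      floor: float = 1e-8) -> float:
    """Method-of-moments NB dispersion pooled across features, from
    within-group residuals (variance = mu + alpha * mu^2)."""
    num = 0.0
    den = 0.0
    for idx in group_idx:
        g = norm[:, idx]
        n = g.shape[1]
        if n < 2:
            continue
        m = g.mean(axis=1)
        v = g.var(axis=1, ddof=1)
        num += float(np.sum((n - 1) * (v - m)))
        den += float(np.sum((n - 1) * m ** 2))
    if den <= 0:
        return floor
    return max(num / den, floor)


def nb_wald_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    levels: Tuple[str, str],
    dispersion: float | None = None,
    p0: float = 1.0,
    cfg: Config | None = None,
) -> pd.DataFrame:
    """Negative-binomial Wald test of condition B over A.

    Counts are normalized by median-of-ratios size factors; the NB dispersion
    (variance = mu + alpha mu^2) is a single method-of-moments estimate
    pooled across features from within-group residuals, floored at 1e-8
    (pass ``dispersion`` to override).  Per feature,
    ``log2FC = log2(m_B / m_A)`` (a pseudocount of ``p0`` normalized units is
    added to both means when either is zero), the delta-method standard
    error is ``SE = (1/ln 2) sqrt(1/(n_A m_A) + alpha/n_A + 1/(n_B m_B) +
    alpha/n_B)``, p is the two-sided normal tail of ``log2FC/SE`` and q its
    BH adjustment.  Calls use the configured thresholds
    (|log2FC| >= lfc_min and q <= fdr_max, boundaries inclusive).
    """
    cfg = cfg or Config()
    groups = pd.Series(groups)
    a_label, b_label = levels
    a_ids = [s for s in counts.columns if groups.get(s) == a_label]
    b_ids = [s for s in counts.columns if groups.get(s) == b_label]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("need >= 2 samples per group")

    sub = counts[a_ids + b_ids]
    nonzero = sub.sum(axis=1) > 0
    sub_nz = sub[nonzero]
    s = size_factors(sub_nz)
    norm = sub_nz.to_numpy(dtype=float) / s.to_numpy()
    n_a, n_b = len(a_ids), len(b_ids)
    ia = np.arange(n_a)
    ib = np.arange(n_a, n_a + n_b)

    alpha = dispersion
    if alpha is None:
        alpha = pooled_dispersion(norm, [ia, ib])

    m_a = norm[:, ia].mean(axis=1)
    m_b = norm[:, ib].mean(axis=1)
    zero = (m_a == 0) | (m_b == 0)
    m_a_eff = np.where(zero, m_a + p0, m_a)
    m_b_eff = np.where(zero, m_b + p0, m_b)
    lfc = np.log2(m_b_eff / m_a_eff)
    se = np.sqrt(1.0 / (n_a * m_a_eff) + alpha / n_a
                 + 1.0 / (n_b * m_b_eff) + alpha / n_b) / LN2
    z = np.divide(lfc, se, out=np.zeros_like(lfc), where=se > 0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    q = bh_adjust(p)

    call = np.full(len(lfc), "NE", dtype=object)
    call[(lfc >= cfg.lfc_min) & (q <= cfg.fdr_max)] = "up_in_B"
    call[(lfc <= -cfg.lfc_min) & (q <= cfg.fdr_max)] = "up_in_A"

    res = pd.DataFrame({
        "baseMean": norm.mean(axis=1),
        "log2FC": lfc,
        "lfcSE": se,
        "p": p,
        "q": q,
        "call": call,
    }, index=sub_nz.index)
    # all-zero features are untestable: NaN statistics, NE call
    if (~nonzero).any():
        empty = pd.DataFrame({
            "baseMean": 0.0, "log2FC": np.nan, "lfcSE": np.nan,
            "p": np.nan, "q": np.nan, "call": "NE",
        }, index=sub.index[~nonzero])
        res = pd.concat([res, empty]).loc[counts.index]
    res.attrs["dispersion"] = float(alpha)
    res.attrs["levels"] = (a_label, b_label)
    return res


def classify_pirnas(de: pd.DataFrame, cfg: Config | None = None) -> pd.Series:
    """Sex class per locus from a DE table computed with
    A = oogenesis, B = spermatogenesis.

    male: log2FC >= +lfc_min and q <= fdr_max; female: log2FC <= -lfc_min
    and q <= fdr_max; otherwise NE.  Boundaries are inclusive.
    """
    cfg = cfg or Config()
    if "q" not in de.columns:
        raise ValueError("DE table lacks q values; run nb_wald_test first")
    lfc = de["log2FC"]
    q = de["q"]
    cls = pd.Series("NE", index=de.index, name="sex_class", dtype=object)
    cls[(lfc >= cfg.lfc_min) & (q <= cfg.fdr_max)] = "male"
    cls[(lfc <= -cfg.lfc_min) & (q <= cfg.fdr_max)] = "female"
    return cls


def set_overlap(
    calls_a: Mapping[str, str] | pd.Series,
    calls_b: Mapping[str, str] | pd.Series,
    classes: Iterable[str] = ("male", "female"),
) -> pd.DataFrame:
    """Overlap of two classifications, per class of interest.

    Reports |A|, |B|, the intersection and set differences, and the fraction
    |A & B| / |A| -- the statistic behind "82% of male piRNAs were also
    identified previously".
    """
    calls_a = pd.Series(calls_a)
    calls_b = pd.Series(calls_b)
    rows = []
    for cls in classes:
        set_a = set(calls_a.index[calls_a == cls])
        set_b = set(calls_b.index[calls_b == cls])
        inter = len(set_a & set_b)
        rows.append({
            "class": cls,
            "n_A": len(set_a),
            "n_B": len(set_b),
            "intersection": inter,
            "only_A": len(set_a - set_b),
            "only_B": len(set_b - set_a),
            "fraction_of_A": inter / len(set_a) if set_a else np.nan,
        })
    return pd.DataFrame(rows).set_index("class")
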