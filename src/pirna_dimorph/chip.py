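"""ChIP quantification over 1 kb genome bins.

The procedure: reads are extended to the average fragment length (200 bp),
the genome is partitioned into consecutive non-overlapping 1 kb bins, per-bin
coverage is depth-normalized to counts per million (excluding configured
chromosomes, e.g. MtDNA, from the depth), bins whose IP coverage falls below
the median input coverage of piRNA-depleted bins on the piRNA chromosome are
excluded, IP/input ratios are formed with a pseudocount, differential bins
are called between genotypes with a fold threshold, bins are classified by
the sex class of the piRNAs they contain (membership by piRNA 5' nucleotide),
cluster enrichment is tested with the rank-sum test, and binding profiles /
heatmaps are anchored on piRNA 5' nucleotides at 50 bp resolution.

Fragment-to-bin weighting is proportional to overlapped bp, so each fragment
contributes total weight 1 across bins (a ``split=False`` mode counts a
fragment fully in every overlapped bin instead, for compatibility with plain
overlap counting).
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import Config
from .intervals import GenomicInterval
from .stats import wilcoxon_rank_sum

log = logging.getLogger(__name__)

BIN_CLASSES = ("all_male", "all_female", "all_NE", "mixed", "none")


def extend_reads(reads: pd.DataFrame, frag_len: int,
                 chrom_sizes: Mapping[str, int]) -> pd.DataFrame:
    """Extend each read to ``frag_len`` bp in its 3' direction, clipped to
    the chromosome.  Reads already longer than ``frag_len`` are returned
    unextended with a warning."""
    out = reads.copy()
    lengths = out["end"] - out["start"]
    too_long = lengths > frag_len
    if too_long.any():
        warnings.warn(f"{int(too_long.sum())} reads longer than frag_len="
                      f"{frag_len} left unextended")
    plus = (out["strand"] == "+") & ~too_long
    minus = (out["strand"] == "-") & ~too_long
    out.loc[plus, "end"] = out.loc[plus, "start"] + frag_len
    out.loc[minus, "start"] = out.loc[minus, "end"] - frag_len
    sizes = out["chrom"].map(chrom_sizes)
    out["start"] = np.maximum(out["start"], 0)
    out["end"] = np.minimum(out["end"], sizes)
    return out


def make_bins(chrom_sizes: Mapping[str, int], bin_size: int) -> pd.DataFrame:
    """Tile each chromosome with consecutive non-overlapping bins; the last
    bin of a chromosome may be shorter."""
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        starts = np.arange(0, size, bin_size)
        ends = np.minimum(starts + bin_size, size)
        rows.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def bin_coverage(
    fragments: pd.DataFrame,
    bins: pd.DataFrame,
    bin_size: int,
    split: bool = True,
) -> pd.Series:
    """Raw per-bin coverage of (extended) fragments.

    With ``split=True`` each fragment distributes its weight over the bins it
    overlaps proportionally to overlapped bp (mass-conserving); with
    ``split=False`` it counts fully in every overlapped bin.
    """
    if len(fragments) == 0 or float(fragments["weight"].sum()) == 0:
        raise ValueError("zero total fragments")
    raw = np.zeros(len(bins), dtype=float)
    offsets = {}
    pos = 0
    for chrom, grp in bins.groupby("chrom", sort=False):
        offsets[chrom] = (pos, int(grp["end"].max()))
        pos += len(grp)
    for chrom, grp in fragments.groupby("chrom", sort=False):
        if chrom not in offsets:
            continue
        base, chrom_end = offsets[chrom]
        start = np.minimum(grp["start"].to_numpy(), chrom_end - 1)
        end = np.minimum(grp["end"].to_numpy(), chrom_end)
        weight = grp["weight"].to_numpy(dtype=float)
        flen = (end - start).astype(float)
        b0 = start // bin_size
        b1 = (end - 1) // bin_size
        max_span = int((b1 - b0).max()) + 1
        for o in range(max_span):
            b = b0 + o
            m = b <= b1
            if not m.any():
                break
            lo = np.maximum(start[m], b[m] * bin_size)
            hi = np.minimum(end[m], (b[m] + 1) * bin_size)
            if split:
                contrib = weight[m] * (hi - lo) / flen[m]
            else:
                contrib = weight[m]
            np.add.at(raw, base + b[m], contrib)
    return pd.Series(raw, index=bins.index, name="raw")


def normalize_coverage(
    raw: pd.Series,
    fragments: pd.DataFrame,
    bins: pd.DataFrame,
    exclude_chroms: Sequence[str] = ("MtDNA",),
) -> pd.Series:
    """Per-million depth normalization; the library depth counts fragment
    weight on all chromosomes except ``exclude_chroms``."""
    keep = ~fragments["chrom"].isin(exclude_chroms)
    total = float(fragments.loc[keep, "weight"].sum())
    if total <= 0:
        raise ValueError("zero usable fragments after chromosome exclusion")
    return (raw * 1e6 / total).rename("cpm")


def coverage_track(
    reads: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    cfg: Config,
    bin_size: Optional[int] = None,
    extend: bool = True,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Convenience: extend reads, bin, depth-normalize.  Returns
    ``(bins, cpm)``; ``bin_size`` defaults to the 1 kb analysis bins."""
    bin_size = bin_size or cfg.bin_size
    frags = extend_reads(reads, cfg.frag_len, chrom_sizes) if extend else reads
    bins = make_bins(chrom_sizes, bin_size)
    raw = bin_coverage(frags, bins, bin_size)
    cpm = normalize_coverage(raw, frags, bins, cfg.cpm_exclude_chroms)
    return bins, cpm


def pirna_5p_bin_counts(bins: pd.DataFrame, loci: pd.DataFrame,
                        bin_size: int) -> pd.DataFrame:
    """Number of piRNA 5' nucleotides per bin, split by sex class.

    A locus spanning a bin boundary counts only in the bin holding its 5' nt,
    keeping bin classification consistent with 5'-anchored profiles.
    """
    classes = ["male", "female", "NE", "unassigned"]
    arrays = {cls: np.zeros(len(bins), dtype=np.int64) for cls in classes}
    base_of = {}
    pos = 0
    for chrom, grp in bins.groupby("chrom", sort=False):
        base_of[chrom] = pos
        pos += len(grp)
    for chrom, grp in loci.groupby("chrom", sort=False):
        if chrom not in base_of:
            continue
        p5 = np.where(grp["strand"] == "-", grp["end"] - 1, grp["start"])
        b = base_of[chrom] + p5 // bin_size
        for cls in classes:
            sel = (grp["sex_class"] == cls).to_numpy()
            np.add.at(arrays[cls], b[sel], 1)
    return pd.DataFrame(arrays, index=bins.index)


def exclusion_filter(
    ip_cpm: pd.Series,
    input_cpm: pd.Series,
    bins: pd.DataFrame,
    loci: pd.DataFrame,
    chrom: str,
    bin_size: int,
) -> Tuple[pd.Series, float]:
    """The input-median exclusion filter.

    Threshold T = median input coverage over bins on ``chrom`` containing no
    piRNA 5' nucleotide ("piRNA-depleted"); a bin is excluded iff its IP
    coverage is strictly below T.  Returns ``(excluded flags, T)``.
    """
    p5 = pirna_5p_bin_counts(bins, loci, bin_size).sum(axis=1)
    depleted = (p5 == 0) & (bins["chrom"] == chrom)
    if not depleted.any():
        raise ValueError(f"no piRNA-depleted bins on {chrom}")
    threshold = float(input_cpm[depleted].median())
    excluded = (ip_cpm < threshold).rename("excluded")
    log.info("exclusion_filter: T=%.4g, %d of %d bins excluded",
             threshold, int(excluded.sum()), len(excluded))
    return excluded, threshold


def bin_ratio(ip_cpm: pd.Series, input_cpm: pd.Series,
              pseudocount: float = 1.0) -> pd.Series:
    """IP/input ratio with a pseudocount in normalized units:
    ``(ip + eps) / (input + eps)``."""
    return ((ip_cpm + pseudocount) / (input_cpm + pseudocount)).rename("ratio")


def call_differential_bins(
    ratio_case: pd.Series,
    ratio_control: pd.Series,
    fold: float = 2.0,
    direction: str = "enriched",
    eligible: Optional[pd.Series] = None,
) -> pd.Series:
    """Differential bins between two genotypes' IP/input ratios.

    ``enriched``: ratio_case >= fold x ratio_control;
    ``depleted``: ratio_case <= ratio_control / fold.  ``eligible`` masks the
    analyzable bin set (typically the non-excluded bins of the reference IP
    sample); ineligible bins are never called.  By construction
    ``enriched(case, control) == depleted(control, case)`` on a fixed mask.
    """
    if direction not in ("enriched", "depleted"):
        raise ValueError(f"unknown direction {direction!r}")
    if not ratio_case.index.equals(ratio_control.index):
        raise ValueError("case and control ratios cover different bin sets")
    if eligible is None:
        eligible = ratio_case.notna() & ratio_control.notna()
    if direction == "enriched":
        called = ratio_case >= fold * ratio_control
    else:
        called = ratio_case <= ratio_control / fold
    return (called & eligible.astype(bool)).rename(direction)


def classify_bins(bins: pd.DataFrame, loci: pd.DataFrame,
                  bin_size: int) -> pd.Series:
    """piRNA-content class per bin: ``all_male`` / ``all_female`` / ``all_NE``
    if the bin holds >= 1 piRNA 5' nt and all of one class, ``mixed``
    otherwise, ``none`` with zero piRNAs."""
    counts = pirna_5p_bin_counts(bins, loci, bin_size)
    pirna = counts[["male", "female", "NE"]]
    total = pirna.sum(axis=1)
    out = pd.Series("mixed", index=bins.index, name="pirna_content",
                    dtype=object)
    out[total == 0] = "none"
    for cls in ("male", "female", "NE"):
        out[(pirna[cls] == total) & (total > 0)] = f"all_{cls}"
    return out


def cluster_wilcoxon(
    ratio: pd.Series,
    bins: pd.DataFrame,
    cluster_intervals: Sequence[GenomicInterval],
    chrom: str,
    excluded: Optional[pd.Series] = None,
) -> Dict[str, float]:
    """Rank-sum test of bin ratios inside vs outside the piRNA clusters on
    ``chrom``, restricted to non-excluded bins."""
    on_chrom = bins["chrom"] == chrom
    usable = on_chrom & ratio.notna()
    if excluded is not None:
        usable &= ~excluded.astype(bool)
    inside = pd.Series(False, index=bins.index)
    for iv in cluster_intervals:
        inside |= ((bins["chrom"] == iv.chrom)
                   & (bins["start"] < iv.end) & (bins["end"] > iv.start))
    x = ratio[usable & inside].to_numpy()
    y = ratio[usable & ~inside].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group: no usable bins inside or outside "
                         "the clusters")
    u, p = wilcoxon_rank_sum(x, y, mode="auto")
    return {"U": u, "p": p, "n_inside": int(len(x)), "n_outside": int(len(y))}


# ---------------------------------------------------------------------------
# anchored profiles
# ---------------------------------------------------------------------------

def _window_means(vals: np.ndarray, track_bin: int, g0: np.ndarray,
                  g1: np.ndarray) -> np.ndarray:
    """bp-weighted mean of a binned track over genomic windows [g0, g1)."""
    prefix = np.concatenate([[0.0], np.cumsum(vals * float(track_bin))])

    def integral(x):
        b = x // track_bin
        rem = x - b * track_bin
        return prefix[b] + vals[np.minimum(b, len(vals) - 1)] * rem

    return (integral(g1) - integral(g0)) / (g1 - g0)


def anchored_profile(
    track: pd.Series,
    track_bins: pd.DataFrame,
    track_bin_size: int,
    anchors: pd.DataFrame,
    flank: int = 500,
    profile_bin: int = 50,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Strand-aware signal profile around piRNA 5' nucleotides.

    Per anchor the track is sampled over ``[5' - flank, 5' + flank)`` in
    ``profile_bin`` steps, minus-strand anchors reversed so upstream is
    always on the left and position 0 is the 5' nt.  Returns
    ``(profile, heatmap)``: the profile has the across-anchor mean, standard
    error and n per step; the heatmap matrix has one row per anchor, sorted
    by descending row mean.  Anchors whose window runs off the chromosome
    are dropped with a warning.
    """
    if flank % profile_bin != 0:
        raise ValueError("flank must be a multiple of profile_bin")
    positions = np.arange(-flank, flank, profile_bin)
    per_chrom: Dict[str, np.ndarray] = {}
    chrom_len: Dict[str, int] = {}
    for chrom, grp in track_bins.groupby("chrom", sort=False):
        per_chrom[chrom] = track[grp.index].to_numpy(dtype=float)
        chrom_len[chrom] = int(grp["end"].max())

    rows = []
    ids = []
    dropped = 0
    for a in anchors.itertuples(index=False):
        if a.chrom not in per_chrom:
            dropped += 1
            continue
        p5 = a.end - 1 if a.strand == "-" else a.start
        L = chrom_len[a.chrom]
        if p5 - flank < 0 or p5 + flank > L:
            dropped += 1
            continue
        if a.strand == "-":
            g0 = p5 - positions - profile_bin + 1
            g1 = p5 - positions + 1
        else:
            g0 = p5 + positions
            g1 = g0 + profile_bin
        rows.append(_window_means(per_chrom[a.chrom], track_bin_size, g0, g1))
        ids.append(getattr(a, "id", str(len(ids))))
    if dropped:
        warnings.warn(f"anchored_profile: dropped {dropped} anchors with "
                      "windows off the chromosome")
    if not rows:
        raise ValueError("no usable anchors")
    mat = pd.DataFrame(np.vstack(rows), index=ids, columns=positions)
    mean = mat.mean(axis=0)
    if len(mat) > 1:
        se = mat.std(axis=0, ddof=1) / np.sqrt(len(mat))
    else:
        se = pd.Series(0.0, index=mat.columns)
    profile = pd.DataFrame({
        "position": positions, "mean": mean.to_numpy(),
        "se": se.to_numpy(), "n": len(mat),
    })
    heatmap = mat.loc[mat.mean(axis=1).sort_values(ascending=False).index]
    return profile, heatmap


def profile_baseline(profile: pd.DataFrame, edge_fraction: float = 0.25
                     ) -> float:
    """Baseline of a profile: mean signal over the outer ``edge_fraction``
    of positions on each side."""
    k = max(1, int(len(profile) * edge_fraction))
    vals = profile["mean"].to_numpy()
    return float(np.concatenate([vals[:k], vals[-k:]]).mean())
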