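"""Upstream core-motif statistics.

piRNA promoters carry a conserved 8 nt core (Ruby) motif, NNGTTTCA, a few bp
upstream of the piRNA 5' nucleotide; male-biased piRNAs additionally show a
cytosine at the motif's 5'-most position (CNGTTTCA).  Because the motif is a
fixed-width 8-mer, discovery here is exact k-mer enumeration with a binomial
E-value (one hit per sequence counts, ZOOPS-like) rather than an EM motif
suite: complete, deterministic, and oracle-checkable.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Genome, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class MotifModel:
    """A fixed-width motif: PWM, background, consensus and occurrences.

    ``occurrences`` holds ``(sequence id, offset, matched word)`` where the
    offset places the motif's first base relative to the piRNA 5' nt
    (upstream negative; the last character of each upstream window abuts the
    5' nt).
    """

    pwm: pd.DataFrame              # k rows x ACGT columns, rows sum to 1
    background: pd.Series          # ACGT frequencies
    consensus: str
    occurrences: pd.DataFrame      # id, offset, word
    n_sequences: int
    e_value: Optional[float] = None

    @property
    def k(self) -> int:
        return len(self.pwm)

    def cover_pattern(self) -> str:
        """Per-column IUPAC code covering every base observed in the
        recorded occurrences; scanning with it re-finds them all."""
        cols = []
        for j in range(self.k):
            seen = sorted({w[j] for w in self.occurrences["word"]})
            cols.append(_iupac_of(seen))
        return "".join(cols)


def upstream_sequences(
    loci: pd.DataFrame, genome: Genome, upstream_len: int = 60
) -> pd.Series:
    """Per-locus upstream window, oriented so its last base is adjacent to
    the piRNA 5' nucleotide.

    Plus strand: ``genome[start - L, start)``; minus strand: reverse
    complement of ``genome[end, end + L)``.  Loci whose window runs off the
    chromosome are dropped with a warning.
    """
    out = {}
    dropped = 0
    for row in loci.itertuples(index=False):
        if row.chrom not in genome:
            raise KeyError(f"unknown chromosome {row.chrom!r}")
        size = len(genome.seqs[row.chrom])
        if row.strand == "-":
            if row.end + upstream_len > size:
                dropped += 1
                continue
            seq = revcomp(genome.fetch(row.chrom, row.end,
                                       row.end + upstream_len))
        else:
            if row.start - upstream_len < 0:
                dropped += 1
                continue
            seq = genome.fetch(row.chrom, row.start - upstream_len, row.start)
        out[row.id] = seq
    if dropped:
        warnings.warn(f"upstream_sequences: dropped {dropped} loci with "
                      "windows off the chromosome")
    return pd.Series(out, name="upstream", dtype=object)


def base_frequencies(seqs: Sequence[str]) -> pd.Series:
    joined = "".join(seqs)
    n = len(joined)
    return pd.Series(
        {b: joined.count(b) / n for b in "ACGT"}, name="background")


def top_kmer(
    seqs: Sequence[str],
    k: int = 8,
    background: Optional[pd.Series] = None,
) -> Tuple[str, int, float]:
    """Most significant k-mer by binomial E-value.

    For each k-mer, n = number of sequences containing at least one match;
    with per-sequence hit probability ``1 - (1 - q)^(L - k + 1)`` (q the
    product of background frequencies of the k-mer's bases), p is the
    one-sided binomial tail P(X >= n) and E = p * 4^k.  Ties break to the
    lexicographically smallest k-mer.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences")
    if min(len(s) for s in seqs) < k:
        raise ValueError(f"k={k} exceeds the shortest sequence")
    bg = background if background is not None else base_frequencies(seqs)

    present: Dict[str, int] = {}
    for s in seqs:
        seen = {s[i:i + k] for i in range(len(s) - k + 1)}
        for kmer in seen:
            present[kmer] = present.get(kmer, 0) + 1

    kmers = sorted(present)  # lexicographic order settles E-value ties
    counts = np.array([present[m] for m in kmers])
    # clamp background away from {0, 1} so q stays a usable probability
    log_q = np.array([
        sum(np.log(min(max(bg[b], 1e-12), 1 - 1e-12)) for b in m)
        for m in kmers
    ])
    n_windows = np.array([len(s) - k + 1 for s in seqs])
    # per-sequence hit probability differs if lengths differ; use the mean
    # window count (lengths are equal for upstream windows)
    w = float(n_windows.mean())
    p_hit = 1.0 - np.exp(w * np.log1p(-np.exp(log_q)))
    p = sps.binom.sf(counts - 1, len(seqs), p_hit)
    e = p * (4.0 ** k)
    best = int(np.lexsort((np.array(kmers), e))[0])
    return kmers[best], int(counts[best]), float(e[best])


def _pattern_regex(pattern: str) -> re.Pattern:
    try:
        return re.compile("".join(
            f"[{IUPAC[b]}]" if len(IUPAC[b]) > 1 else IUPAC[b]
            for b in pattern.upper()
        ))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in pattern: {exc}") from exc


def build_pwm(
    seqs: Mapping[str, str] | pd.Series,
    kmer: str,
    pseudocount: float = 0.25,
    background: Optional[pd.Series] = None,
) -> MotifModel:
    """Locate the leftmost match of ``kmer`` (IUPAC allowed, e.g. NNGTTTCA)
    in each sequence and build a PWM over the matched windows.

    Column frequencies carry a pseudocount of ``pseudocount`` per base;
    sequences without a match are excluded and counted.  Offsets are
    reported with the piRNA 5' nt at 0 and upstream negative, i.e.
    ``match_start - len(sequence)``.
    """
    seqs = pd.Series(seqs)
    k = len(kmer)
    rx = _pattern_regex(kmer)
    occ_rows: List[Tuple[str, int, str]] = []
    for sid, s in seqs.items():
        m = rx.search(s.upper())
        if m is None:
            continue
        occ_rows.append((sid, m.start() - len(s), m.group(0)))
    if not occ_rows:
        raise ValueError(f"no occurrences of {kmer!r} in {len(seqs)} sequences")
    occurrences = pd.DataFrame(occ_rows, columns=["id", "offset", "word"])

    counts = np.full((k, 4), pseudocount, dtype=float)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for word in occurrences["word"]:
        for j, b in enumerate(word):
            counts[j, base_idx[b]] += 1.0
    pwm = pd.DataFrame(counts / counts.sum(axis=1, keepdims=True),
                       columns=list("ACGT"))
    consensus = "".join(
        pwm.columns[np.argmax(row)] if row.max() >= 0.5 else
        _iupac_of(pwm.columns[row >= 0.25])
        for _, row in pwm.iterrows()
    )
    bg = background if background is not None else base_frequencies(list(seqs))
    return MotifModel(
        pwm=pwm, background=bg, consensus=consensus,
        occurrences=occurrences, n_sequences=len(seqs),
    )


def _iupac_of(bases) -> str:
    key = "".join(sorted(bases))
    inv = {"".join(sorted(v)): c for c, v in IUPAC.items()}
    return inv.get(key, "N")


def c_bias(model: MotifModel) -> Tuple[float, float]:
    """Fraction of motif occurrences with C at position 1 and a two-sided
    binomial p against the background C frequency -- the statistic behind
    the male-specific CNGTTTCA signature."""
    if len(model.occurrences) == 0:
        raise ValueError("model has no occurrences")
    first = model.occurrences["word"].str[0]
    n_c = int((first == "C").sum())
    n = len(first)
    p = sps.binomtest(n_c, n, float(model.background["C"]),
                      alternative="two-sided").pvalue
    return n_c / n, float(p)


def motif_offset_stats(model: MotifModel) -> Tuple[float, float]:
    """Median and interquartile range of the motif position-1 offset (piRNA
    5' nt at 0, upstream negative)."""
    off = model.occurrences["offset"].to_numpy(dtype=float)
    q1, med, q3 = np.percentile(off, [25, 50, 75])
    return float(med), float(q3 - q1)
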