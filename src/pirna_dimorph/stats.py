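"""Shared statistical primitives.

Thin, validated fronts over scipy/statsmodels with the mode-selection rules
this pipeline relies on.  Exact p-values are never floored; the tests
cross-check these against brute-force enumeration oracles.
"""

from __future__ import annotations

import warnings
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: exact Mann-Whitney enumeration is used up to this combined sample size
EXACT_RANKSUM_N = 20


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney / Wilcoxon rank-sum test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic for ``x``.
    ``mode='auto'`` enumerates the exact null when the combined sample size
    is <= 20 and there are no ties, otherwise uses the normal approximation
    with midrank tie correction and continuity correction.  Exact mode
    refuses ties (enumeration under ties is ambiguous) and falls back to the
    approximation with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")

    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size

    method = "asymptotic"
    if mode == "exact" or (mode == "auto" and x.size + y.size <= EXACT_RANKSUM_N):
        if has_ties:
            if mode == "exact":
                warnings.warn(
                    "ties present: exact rank-sum enumeration refused, "
                    "falling back to the normal approximation"
                )
        else:
            method = "exact"

    if np.all(combined == combined[0]):
        # identical constant samples: U is the midrank value, p = 1
        return float(x.size * y.size / 2.0), 1.0

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (hypergeometric
    summation of tables at most as probable as the observed one)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cells must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("cells must be integers")
    t = np.round(t).astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
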