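"""Spectral-count IP-MS enrichment.

Per sample, peptide counts are normalized to fractions of the sample total;
enrichment is the log2 ratio of mean IP fraction to mean control fraction
(with a pseudofraction guarding absent proteins), and significance comes
from a pooled Fisher exact test per protein with Bonferroni adjustment --
an exact, assumption-light test for spectral counts.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import fisher_exact_2x2


def _split_arms(table: pd.DataFrame, ip_samples: Sequence[str],
                control_samples: Sequence[str]) -> None:
    if not ip_samples or not control_samples:
        raise ValueError("need >= 1 IP and >= 1 control sample")
    missing = (set(ip_samples) | set(control_samples)) - set(table.columns)
    if missing:
        raise ValueError(f"samples not in table: {sorted(missing)}")


def normalize_peptides(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample peptide fractions: count / sample total (columns sum to 1)."""
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total samples: {bad}")
    if (table < 0).to_numpy().any():
        raise ValueError("peptide counts must be >= 0")
    return table / totals


def enrichment_table(
    table: pd.DataFrame,
    ip_samples: Sequence[str],
    control_samples: Sequence[str],
    pseudofraction: Optional[float] = None,
) -> pd.DataFrame:
    """log2 IP-over-control enrichment of mean peptide fractions.

    ``pseudofraction`` defaults to 1 / (largest sample total): one peptide
    in the deepest sample, keeping proteins absent from one arm finite.
    """
    _split_arms(table, ip_samples, control_samples)
    if pseudofraction is None:
        pseudofraction = 1.0 / float(table.sum(axis=0).max())
    frac = normalize_peptides(table)
    mean_ip = frac[list(ip_samples)].mean(axis=1)
    mean_ctrl = frac[list(control_samples)].mean(axis=1)
    enrich = np.log2((mean_ip + pseudofraction) / (mean_ctrl + pseudofraction))
    return pd.DataFrame({
        "mean_ip_fraction": mean_ip,
        "mean_control_fraction": mean_ctrl,
        "log2_enrichment": enrich,
    })


def protein_significance(
    table: pd.DataFrame,
    ip_samples: Sequence[str],
    control_samples: Sequence[str],
) -> pd.DataFrame:
    """Per-protein Fisher exact test on pooled counts with Bonferroni
    adjustment.

    Counts are pooled across replicates within each arm; each protein is
    tested as the 2x2 table [protein vs rest] x [IP vs control].  Proteins
    with zero counts everywhere are dropped before the correction (an
    untestable row would only inflate the Bonferroni factor); degenerate
    margins are reported with p = 1 and a flag.
    """
    _split_arms(table, ip_samples, control_samples)
    ip_total = table[list(ip_samples)].sum(axis=1)
    ctrl_total = table[list(control_samples)].sum(axis=1)
    keep = (ip_total + ctrl_total) > 0
    ip_total = ip_total[keep]
    ctrl_total = ctrl_total[keep]
    grand_ip = float(ip_total.sum())
    grand_ctrl = float(ctrl_total.sum())
    n_tests = int(keep.sum())

    pvals = np.ones(n_tests)
    degenerate = np.zeros(n_tests, dtype=bool)
    for i, (a, b) in enumerate(zip(ip_total.to_numpy(),
                                   ctrl_total.to_numpy())):
        t = [[a, grand_ip - a], [b, grand_ctrl - b]]
        try:
            pvals[i] = fisher_exact_2x2(t)
        except ValueError:
            degenerate[i] = True
    out = pd.DataFrame({
        "p": pvals,
        "p_bonferroni": np.minimum(pvals * n_tests, 1.0),
        "degenerate": degenerate,
    }, index=ip_total.index)
    return out


def volcano_table(
    table: pd.DataFrame,
    ip_samples: Sequence[str],
    control_samples: Sequence[str],
    pseudofraction: Optional[float] = None,
) -> pd.DataFrame:
    """Volcano-style output: one row per protein with >= 1 nonzero count,
    log2 enrichment and (adjusted) p."""
    keep = table.sum(axis=1) > 0
    sub = table[keep]
    enr = enrichment_table(sub, ip_samples, control_samples, pseudofraction)
    sig = protein_significance(sub, ip_samples, control_samples)
    return enr.join(sig)
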