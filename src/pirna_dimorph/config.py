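"""Analysis configuration.

Every printed threshold of the analysis lives here: the 15-30 nt read-length
window, the log2 fold-change (0.26, i.e. 1.2-fold) and FDR (0.05) cutoffs for
calling sex-biased piRNAs, the 200 bp ChIP fragment extension, the 1 kb
quantification bins and 50 bp profile bins, and the 60 nt upstream window for
motif work.  Parameters without a published value (ratio pseudocount, the
differential-bin fold, the motif-to-5'-nt gap) are package defaults and are
documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List

import yaml

from .intervals import GenomicInterval

#: Toy chromosome IV used by the synthetic generator: an ~1:2 scale model of
#: the real 17.5 Mb chromosome with its two piRNA clusters.
DEFAULT_CHROM = "chrIV"
DEFAULT_CHROM_LEN = 8_000_000
DEFAULT_CLUSTERS = (
    GenomicInterval(DEFAULT_CHROM, 1_500_000, 2_400_000),  # small cluster
    GenomicInterval(DEFAULT_CHROM, 4_600_000, 6_200_000),  # big cluster
)


@dataclass
class Config:
    read_len_min: int = 15
    read_len_max: int = 30
    lfc_min: float = 0.26
    fdr_max: float = 0.05
    frag_len: int = 200
    bin_size: int = 1000
    profile_bin: int = 50
    profile_flank: int = 500
    upstream_len: int = 60
    motif_k: int = 8
    motif_gap: int = 2
    pseudocount: float = 1.0
    cpm_exclude_chroms: List[str] = field(default_factory=lambda: ["MtDNA"])
    diff_bin_fold: float = 2.0
    cluster_intervals: List[GenomicInterval] = field(
        default_factory=lambda: list(DEFAULT_CLUSTERS)
    )

    def __post_init__(self) -> None:
        for name in ("read_len_min", "read_len_max", "frag_len", "bin_size",
                     "profile_bin", "profile_flank", "upstream_len", "motif_k",
                     "motif_gap"):
            if getattr(self, name) <= 0 and name != "motif_gap":
                raise ValueError(f"{name} must be positive")
        if self.read_len_min > self.read_len_max:
            raise ValueError("read_len_min must be <= read_len_max")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if not (0 < self.fdr_max < 1):
            raise ValueError("fdr_max must be in (0, 1)")

    # -- flat key-value (YAML) serialization ------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cluster_intervals"] = [
            f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.cluster_intervals
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        d = dict(d)
        ivs = []
        for s in d.get("cluster_intervals", []):
            if isinstance(s, GenomicInterval):
                ivs.append(s)
                continue
            chrom, rng = s.rsplit(":", 1)
            start, end = rng.split("-")
            ivs.append(GenomicInterval(chrom, int(start), int(end)))
        if ivs or "cluster_intervals" in d:
            d["cluster_intervals"] = ivs
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "Config":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
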