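"""Domain types shared across the package.

All genomic coordinates are 0-based half-open (`[start, end)`), the BED
convention.  GFF3 input (1-based closed) is converted on ingest; nothing
downstream ever sees 1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRANDS = ("+", "-", ".")
SEX_CLASSES = ("male", "female", "NE", "unassigned")
ASSAYS = ("smallRNA", "ChIP_IP", "ChIP_input", "IPMS_IP", "IPMS_control")
CONDITIONS = ("spermatogenesis", "oogenesis")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def five_prime(self) -> int:
        """Position of the 5' nucleotide (start on +, end-1 on -)."""
        if self.strand == "-":
            return self.end - 1
        return self.start


@dataclass(frozen=True)
class PiRNALocus:
    """A piRNA transcription unit (21 nt for mature Type I 21U-RNAs).

    ``motif_offset`` is the position of the first core-motif base relative to
    the piRNA 5' nucleotide (upstream negative); absent for Type II loci,
    which lack the core motif.
    """

    id: str
    interval: GenomicInterval
    sex_class: str = "unassigned"
    pirna_type: str = "I"
    motif_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex_class not in SEX_CLASSES:
            raise ValueError(f"unknown sex_class {self.sex_class!r}")
        if self.pirna_type not in ("I", "II"):
            raise ValueError(f"pirna_type must be 'I' or 'II'")

    @property
    def five_prime(self) -> int:
        return self.interval.five_prime()


@dataclass(frozen=True)
class AlignedRead:
    """One mapped hit of a read.

    ``weight`` is 1 for unique mappers; under proportional multi-mapper
    assignment each of the ``n_hits`` hits carries weight ``1/n_hits`` so the
    weights of one read sum to 1.
    """

    read_id: str
    interval: GenomicInterval
    strand: str
    n_hits: int = 1
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("read strand must be '+' or '-'")
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")
        if not (0 < self.weight <= 1):
            raise ValueError("weight must be in (0, 1]")


@dataclass(frozen=True)
class SampleMeta:
    """One row of the sample sheet."""

    sample_id: str
    condition: str
    genotype: str
    assay: str
    replicate: int

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
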