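"""Genome container, FASTA I/O, and the exact-match toy mapper."""

from __future__ import annotations

from typing import Dict, List, Tuple

from pyfaidx import Fasta

from .intervals import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """An in-memory genome: chromosome name -> uppercase sequence."""

    def __init__(self, seqs: Dict[str, str]):
        self.seqs = {name: s.upper() for name, s in seqs.items()}

    @property
    def sizes(self) -> Dict[str, int]:
        return {name: len(s) for name, s in self.seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self.seqs[chrom]):
            raise ValueError(
                f"window [{start}, {end}) off chromosome {chrom} "
                f"(length {len(self.seqs[chrom])})"
            )
        return self.seqs[chrom][start:end]

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.seqs):
                fh.write(f">{name}\n")
                s = self.seqs[name]
                for i in range(0, len(s), width):
                    fh.write(s[i:i + width] + "\n")


def exact_map(
    seq: str, genome: Genome, max_hits: int = 5
) -> List[Tuple[GenomicInterval, str]]:
    """All exact occurrences of ``seq`` (forward) and its reverse complement
    (minus strand), in deterministic order (chrom, start, '+' before '-'),
    capped at ``max_hits``.

    Stands in for zero-mismatch short-read alignment on the toy genome.  A
    palindromic sequence planted once yields two hits, one per strand.
    """
    if not seq:
        raise ValueError("empty query sequence")
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("query must be over A/C/G/T")
    rc = revcomp(seq)
    hits: List[Tuple[GenomicInterval, str]] = []
    for chrom in sorted(genome.seqs):
        s = genome.seqs[chrom]
        found: List[Tuple[int, str]] = []
        for query, strand in ((seq, "+"), (rc, "-")):
            pos = s.find(query)
            while pos != -1:
                found.append((pos, strand))
                pos = s.find(query, pos + 1)
        found.sort(key=lambda t: (t[0], t[1]))  # '+' sorts before '-'
        for pos, strand in found:
            hits.append(
                (GenomicInterval(chrom, pos, pos + len(seq), strand), strand)
            )
            if len(hits) >= max_hits:
                return hits
    return hits
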