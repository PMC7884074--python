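"""File I/O for the standard formats at the package boundary.

Alignments travel as pandas DataFrames with columns
``chrom, start, end, strand, weight, n_hits`` (plus optional ``read_id``,
``first_nt``); loci as DataFrames with
``id, chrom, start, end, strand, sex_class``.  Coordinates are always
0-based half-open internally; BED is emitted as-is, GFF3 is converted from
1-based closed on ingest.

The BED6 dialect used for alignments stores the hit count of a multi-mapping
read in the score column (0 or empty means a unique hit); locus BED6 carries
the sex class appended to the name field as ``id|class``.
"""

from __future__ import annotations

import re
from typing import Iterable, List, Optional

import pandas as pd

from .intervals import AlignedRead, GenomicInterval, SampleMeta, SEX_CLASSES

READ_COLUMNS = ["chrom", "start", "end", "strand", "weight", "n_hits"]
LOCUS_COLUMNS = ["id", "chrom", "start", "end", "strand", "sex_class"]


class ParseError(ValueError):
    """A malformed record, annotated with its line number when known."""


class ConfigurationError(ValueError):
    pass


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


def _sam_reference_length(cigar: str, seq: str) -> int:
    if cigar != "*":
        n = 0
        consumed = 0
        for length, op in _CIGAR_RE.findall(cigar):
            consumed += len(length) + 1
            if op in _REF_CONSUMING:
                n += int(length)
        if consumed != len(cigar):
            raise ValueError(f"malformed CIGAR {cigar!r}")
        return n
    if seq and seq != "*":
        return len(seq)
    raise ValueError("cannot determine alignment length (CIGAR and SEQ both '*')")


def parse_alignment(
    record: str, dialect: str, line_number: Optional[int] = None
) -> AlignedRead:
    """Parse one alignment record (BED6 or minimal-field SAM) into an
    :class:`AlignedRead`.

    SAM positions are converted from 1-based to 0-based; strand comes from
    the reverse-complement flag bit; the hit count from the ``NH:i`` tag when
    present (absent -> 1, the conservative unique-mapper assumption).
    Unmapped SAM records are rejected.
    """
    where = f" at line {line_number}" if line_number is not None else ""
    fields = record.rstrip("\n").split("\t")
    try:
        if dialect == "BED6":
            if len(fields) < 6:
                raise ValueError("BED6 requires 6 fields")
            chrom, start, end, name, score, strand = fields[:6]
            n_hits = max(1, int(float(score))) if score not in (".", "") else 1
            return AlignedRead(
                read_id=name,
                interval=GenomicInterval(chrom, int(start), int(end), strand),
                strand=strand,
                n_hits=n_hits,
                weight=1.0 / n_hits,
            )
        if dialect == "SAM":
            if len(fields) < 11:
                raise ValueError("SAM requires 11 mandatory fields")
            qname, flag, rname, pos, _mapq, cigar = fields[:6]
            seq = fields[9]
            flag = int(flag)
            if flag & 0x4 or rname == "*":
                raise ValueError("unmapped record")
            strand = "-" if flag & 0x10 else "+"
            start = int(pos) - 1
            length = _sam_reference_length(cigar, seq)
            n_hits = 1
            for tag in fields[11:]:
                if tag.startswith("NH:i:"):
                    n_hits = int(tag[5:])
            return AlignedRead(
                read_id=qname,
                interval=GenomicInterval(rname, start, start + length, strand),
                strand=strand,
                n_hits=n_hits,
                weight=1.0 / n_hits,
            )
    except ParseError:
        raise
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed {dialect} record{where}: {exc}") from exc
    raise ConfigurationError(f"unknown alignment dialect {dialect!r}")


def reads_to_frame(reads: Iterable[AlignedRead]) -> pd.DataFrame:
    rows = [
        (r.interval.chrom, r.interval.start, r.interval.end, r.strand,
         r.weight, r.n_hits, r.read_id)
        for r in reads
    ]
    return pd.DataFrame(rows, columns=READ_COLUMNS + ["read_id"])


def read_alignments(path, dialect: Optional[str] = None) -> pd.DataFrame:
    """Read a BED6 or SAM alignment file into a reads DataFrame.

    The dialect is inferred from the extension when not given; SAM header
    lines (``@``) are skipped.
    """
    path = str(path)
    if dialect is None:
        dialect = "SAM" if path.endswith(".sam") else "BED6"
    reads = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or (dialect == "SAM" and line.startswith("@")):
                continue
            reads.append(parse_alignment(line, dialect, line_number=i))
    return reads_to_frame(reads)


def write_reads_bed(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    if "read_id" not in out.columns:
        out["read_id"] = [f"r{i}" for i in range(len(out))]
    bed = out[["chrom", "start", "end", "read_id"]].copy()
    bed["score"] = out["n_hits"].astype(int)
    bed["strand"] = out["strand"]
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_loci_bed(path) -> pd.DataFrame:
    """Read a locus BED6; a ``|class`` suffix on the name becomes sex_class."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    parts = df["name"].str.split("|", n=1, expand=True)
    ids = parts[0]
    classes = parts[1] if parts.shape[1] > 1 else pd.Series(
        ["unassigned"] * len(df))
    classes = classes.fillna("unassigned")
    bad = set(classes) - set(SEX_CLASSES)
    if bad:
        raise ParseError(f"unknown sex classes in locus BED: {sorted(bad)}")
    out = pd.DataFrame({
        "id": ids, "chrom": df["chrom"], "start": df["start"],
        "end": df["end"], "strand": df["strand"], "sex_class": classes,
    })
    return out


def write_loci_bed(loci: pd.DataFrame, path) -> None:
    bed = pd.DataFrame({
        "chrom": loci["chrom"],
        "start": loci["start"],
        "end": loci["end"],
        "name": loci["id"].astype(str) + "|" + loci["sex_class"].astype(str),
        "score": 0,
        "strand": loci["strand"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_loci_gff3(path) -> pd.DataFrame:
    """Read piRNA loci from GFF3 (1-based closed -> 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "type", "start", "end", "score",
               "strand", "phase", "attributes"],
        dtype={"chrom": str, "attributes": str},
    )
    ids = []
    classes = []
    for attrs in df["attributes"]:
        fields = dict(
            kv.split("=", 1) for kv in str(attrs).split(";") if "=" in kv
        )
        ids.append(fields.get("ID", f"locus{len(ids)}"))
        classes.append(fields.get("sex_class", "unassigned"))
    return pd.DataFrame({
        "id": ids, "chrom": df["chrom"], "start": df["start"] - 1,
        "end": df["end"], "strand": df["strand"], "sex_class": classes,
    })


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "condition", "genotype", "assay", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ParseError("sample_id values must be unique")
    # validate through the dataclass
    for row in df.itertuples(index=False):
        SampleMeta(str(row.sample_id), row.condition, row.genotype,
                   row.assay, int(row.replicate))
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def loci_to_frame(loci: Iterable) -> pd.DataFrame:
    """Convert PiRNALocus objects to the loci DataFrame layout."""
    rows = [
        (l.id, l.interval.chrom, l.interval.start, l.interval.end,
         l.interval.strand, l.sex_class)
        for l in loci
    ]
    return pd.DataFrame(rows, columns=LOCUS_COLUMNS)
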