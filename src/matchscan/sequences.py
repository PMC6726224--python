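"""Sequence and interval I/O: FASTA records, BED/GFF/GTF intervals, strand-aware extraction.

Internal coordinates are 0-based half-open everywhere (BED native); GFF/GTF
1-based closed coordinates are converted on read. Minus-strand extraction
returns the reverse complement.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")

__all__ = [
    "SequenceRecord",
    "GenomicInterval",
    "read_fasta",
    "write_fasta",
    "read_intervals",
    "extract_sequences",
    "reverse_complement",
]


@dataclass
class SequenceRecord:
    id: str
    description: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomicInterval:
    """0-based half-open genomic interval; strand defaults to '+'."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.name:
            self.name = f"{self.chrom}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_sequence(seq: str, rec_id: str) -> str:
    """Uppercase and collapse non-ACGTN (IUPAC ambiguity etc.) to N."""
    seq = seq.upper()
    bad = sum(1 for c in seq if c not in VALID_BASES)
    if bad:
        logger.warning("%s: %d non-ACGTN character(s) mapped to N", rec_id, bad)
        seq = "".join(c if c in VALID_BASES else "N" for c in seq)
    return seq


def _as_handle(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    text = str(source)
    # a path if it exists or looks like one; otherwise treat as pasted FASTA text
    if text and "\n" not in text and (os.path.exists(text) or not text.startswith(">")):
        return open(text)
    return io.StringIO(text)


def read_fasta(source) -> list[SequenceRecord]:
    """Read FASTA from a path, open handle, or pasted text.

    Order is preserved; sequences are uppercased with non-ACGTN characters
    mapped to N (logged). Duplicate ids and empty input are errors.
    """
    handle = _as_handle(source)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq), rec.id)
        if not seq:
            raise ValueError(f"sequence {rec.id!r} is empty")
        records.append(SequenceRecord(id=rec.id, description=rec.description, seq=seq))
    if not records:
        raise ValueError("no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _parse_bed_line(fields: list[str], lineno: int) -> GenomicInterval:
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
    return GenomicInterval(chrom=chrom, start=start, end=end, strand=strand, name=name)


def _parse_gff_line(fields: list[str], lineno: int, fmt: str) -> GenomicInterval:
    if len(fields) < 8:
        raise ValueError(f"line {lineno}: {fmt} needs >= 8 columns")
    chrom = fields[0]
    start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
    end = int(fields[4])
    strand = fields[6] if fields[6] in ("+", "-") else "+"
    name = ""
    if len(fields) > 8:
        attrs = fields[8]
        for key in ("ID=", "Name=", 'gene_id "', 'transcript_id "'):
            if key in attrs:
                raw = attrs.split(key, 1)[1]
                name = raw.split('"')[0] if key.endswith('"') else raw.split(";")[0]
                break
    return GenomicInterval(chrom=chrom, start=start, end=end, strand=strand, name=name)


def read_intervals(source, format: str) -> list[GenomicInterval]:
    """Read genomic intervals from BED (0-based half-open) or GFF/GTF (1-based closed).

    Chromosome names are not validated here; `extract_sequences` checks them
    against the genome. Degenerate (empty) intervals are an error.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF", "GTF"):
        raise ValueError(f"unknown interval format {format!r}")
    handle = _as_handle(source)
    intervals: list[GenomicInterval] = []
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if fmt == "BED":
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 columns")
            intervals.append(_parse_bed_line(fields, lineno))
        else:
            intervals.append(_parse_gff_line(fields, lineno, fmt))
    if not intervals:
        raise ValueError("no intervals found")
    return intervals


def extract_sequences(
    genome: Mapping[str, str] | str | Path,
    intervals: Iterable[GenomicInterval],
) -> list[SequenceRecord]:
    """Fetch interval sequences from a genome, reverse-complementing '-' strand.

    `genome` may be a FASTA path (random access via pyfaidx) or an in-memory
    mapping of chromosome name -> sequence. Intervals that run past a contig
    edge are truncated with a warning; unknown chromosomes are an error,
    reported all at once.
    """
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome), sequence_always_upper=True)
        lengths = {name: len(fa[name]) for name in fa.keys()}

        def fetch(chrom: str, start: int, end: int) -> str:
            return str(fa[chrom][start:end])

    else:
        lengths = {name: len(seq) for name, seq in genome.items()}

        def fetch(chrom: str, start: int, end: int) -> str:
            return genome[chrom][start:end].upper()

    intervals = list(intervals)
    unknown = sorted({iv.chrom for iv in intervals if iv.chrom not in lengths})
    if unknown:
        raise KeyError(f"chromosome(s) not in genome: {', '.join(unknown)}")

    out: list[SequenceRecord] = []
    for iv in intervals:
        start, end = max(iv.start, 0), min(iv.end, lengths[iv.chrom])
        if (start, end) != (iv.start, iv.end):
            logger.warning(
                "%s: truncated to contig bounds [%d, %d)", iv.name, start, end
            )
        seq = _clean_sequence(fetch(iv.chrom, start, end), iv.name)
        if iv.strand == "-":
            seq = reverse_complement(seq)
        out.append(SequenceRecord(id=iv.name, description=iv.name, seq=seq))
    return out
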