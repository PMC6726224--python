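"""TSS annotation table ("gene look-up manager") and promoter extraction.

From an Ensembl-style GTF we build one record per transcript holding its
gene id, gene symbol, transcript id, chromosome, 0-based TSS position and
strand. Gene/transcript identifier lists resolve against this table, and
promoter windows (default 1500 bases upstream to 500 downstream of the TSS,
TSS base included downstream) become strand-aware genomic intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd

from .sequences import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "GlmRecord",
    "PromoterSpec",
    "build_glm",
    "read_glm",
    "write_glm",
    "resolve_ids",
    "promoters",
]

GLM_COLUMNS = ["gene_id", "gene_symbol", "transcript_id", "chrom", "tss", "strand"]


@dataclass(frozen=True)
class GlmRecord:
    gene_id: str
    gene_symbol: str
    transcript_id: str
    chrom: str
    tss: int  # 0-based position of the transcription start base
    strand: str


@dataclass(frozen=True)
class PromoterSpec:
    """Promoter window relative to the TSS, in bases.

    `downstream` counts the TSS base itself, so the default (1500, 500)
    yields a 2000-base promoter.
    """

    upstream: int = 1500
    downstream: int = 500

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("upstream/downstream must be >= 0")
        if self.upstream + self.downstream < 1:
            raise ValueError("promoter window must span at least one base")


def build_glm(gtf: str | Path) -> list[GlmRecord]:
    """Build the TSS table from Ensembl-style GTF text or a GTF file path.

    One record per transcript; the TSS is the transcript's 5' end (GTF start
    for '+' strand, GTF end for '-'), converted to a 0-based coordinate.
    Transcripts missing ids or coordinates are skipped with a warning.
    """
    data = str(gtf)
    from_string = "\n" in data or "\t" in data
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=from_string,
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records: list[GlmRecord] = []
    seen: set[str] = set()
    for feat in db.features_of_type("transcript", order_by=("seqid", "start")):
        try:
            gene_id = feat.attributes["gene_id"][0]
            transcript_id = feat.attributes["transcript_id"][0]
        except KeyError:
            logger.warning("transcript at %s:%d missing gene_id/transcript_id; skipped",
                           feat.seqid, feat.start)
            continue
        if transcript_id in seen:
            logger.warning("duplicate transcript_id %s; keeping first", transcript_id)
            continue
        seen.add(transcript_id)
        symbol = feat.attributes.get("gene_name", [gene_id])[0]
        if feat.strand == "-":
            tss = feat.end - 1  # 1-based end -> 0-based
            strand = "-"
        else:
            tss = feat.start - 1  # 1-based start -> 0-based
            strand = "+"
        records.append(
            GlmRecord(gene_id, symbol, transcript_id, feat.seqid, tss, strand)
        )
    if not records:
        raise ValueError("no transcript records found in GTF")
    return records


def write_glm(records: list[GlmRecord], path: str | Path) -> None:
    """Write the TSS table as a 6-column TSV with header."""
    df = pd.DataFrame([vars(r) if not isinstance(r, GlmRecord) else r.__dict__
                       for r in records], columns=GLM_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_glm(path: str | Path) -> list[GlmRecord]:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in GLM_COLUMNS if c != "tss"})
    missing = [c for c in GLM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TSS table missing column(s): {', '.join(missing)}")
    return [
        GlmRecord(r.gene_id, r.gene_symbol, r.transcript_id, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples(index=False)
    ]


def resolve_ids(
    ids: list[str], glm: list[GlmRecord]
) -> tuple[list[GlmRecord], list[str]]:
    """Match identifiers case-insensitively against gene symbol, gene id, then
    transcript id. Gene-level matches return all of that gene's transcripts.
    Unmatched ids come back in the second return value, never silently dropped."""
    by_symbol: dict[str, list[GlmRecord]] = {}
    by_gene: dict[str, list[GlmRecord]] = {}
    by_transcript: dict[str, list[GlmRecord]] = {}
    for rec in glm:
        by_symbol.setdefault(rec.gene_symbol.lower(), []).append(rec)
        by_gene.setdefault(rec.gene_id.lower(), []).append(rec)
        by_transcript.setdefault(rec.transcript_id.lower(), []).append(rec)

    matched: list[GlmRecord] = []
    unmatched: list[str] = []
    for ident in ids:
        key = ident.strip().lower()
        if not key:
            continue
        recs = by_symbol.get(key) or by_gene.get(key) or by_transcript.get(key)
        if recs:
            matched.extend(recs)
        else:
            unmatched.append(ident)
    return matched, unmatched


def promoters(
    records: list[GlmRecord],
    spec: PromoterSpec = PromoterSpec(),
    one_per_gene: bool = False,
) -> list[GenomicInterval]:
    """Promoter intervals around each TSS, strand-aware and deduplicated.

    '+' strand: [tss - upstream, tss + downstream); '-' strand the mirror
    image, [tss - downstream + 1, tss + upstream + 1), so that after
    reverse-complement extraction the base at offset `upstream` is the TSS
    base on both strands. Intervals are clipped at position 0. With
    `one_per_gene`, only each gene's 5'-most TSS is kept.
    """
    if one_per_gene:
        best: dict[str, GlmRecord] = {}
        for rec in records:
            cur = best.get(rec.gene_id)
            if cur is None:
                best[rec.gene_id] = rec
            elif rec.strand == "+" and rec.tss < cur.tss:
                best[rec.gene_id] = rec
            elif rec.strand == "-" and rec.tss > cur.tss:
                best[rec.gene_id] = rec
        records = list(best.values())

    out: list[GenomicInterval] = []
    seen: set[tuple[str, int, int, str]] = set()
    dups = 0
    for rec in records:
        if rec.strand == "+":
            start = rec.tss - spec.upstream
            end = rec.tss + spec.downstream
        else:
            start = rec.tss - spec.downstream + 1
            end = rec.tss + spec.upstream + 1
        start = max(start, 0)
        if end <= start:
            continue
        key = (rec.chrom, start, end, rec.strand)
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        out.append(
            GenomicInterval(rec.chrom, start, end, rec.strand, name=rec.transcript_id)
        )
    if dups:
        logger.info("deduplicated %d identical promoter interval(s)", dups)
    return out
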