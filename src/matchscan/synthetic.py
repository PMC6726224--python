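"""Seeded synthetic data: genomes, GTF annotations, PFM libraries and
planted-motif sequence sets.

Everything here is reproducible — the same spec and seed give byte-identical
output — so the whole scan/enrichment pipeline can be exercised without any
genome or matrix-library download. Planted sites are exact consensus strings
whose positions and strands are recorded in a truth table, so a scan at
deficit 0 must recover every one of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import PFM, build_scoring_model, ScoringModel
from .sequences import SequenceRecord, reverse_complement

__all__ = ["FixtureSpec", "Fixture", "random_pfm", "random_genome_gtf", "make_fixture"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a planted-motif benchmark.

    planted: (tf_id, query_rate, background_rate) triples — per-sequence
    probabilities of receiving one consensus insertion of that TF.
    Defaults model a typical promoter-set experiment: 50 + 50 sequences of
    600 bases at 45% GC (mammalian promoter-like), one strongly enriched TF.
    """

    seed: int = 0
    n_query: int = 50
    n_background: int = 50
    seq_length: int = 600
    gc_content: float = 0.45
    n_decoy_tfs: int = 4
    motif_length: int = 10
    planted: tuple[tuple[str, float, float], ...] = (("TF_PLANTED", 0.8, 0.1),)

    def __post_init__(self) -> None:
        if self.n_query < 1 or self.n_background < 1:
            raise ValueError("need at least one query and one background sequence")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        for tf, qr, br in self.planted:
            if not (0.0 <= qr <= 1.0 and 0.0 <= br <= 1.0):
                raise ValueError(f"{tf}: planting rates must be in [0, 1]")


@dataclass
class Fixture:
    query: list[SequenceRecord]
    background: list[SequenceRecord]
    pfms: list[PFM]
    models: list[ScoringModel]
    truth: pd.DataFrame  # set, seq_id, tf_id, start, end, strand


def random_pfm(
    rng: np.random.Generator,
    tf_id: str,
    length: int = 10,
    concentration: float = 0.5,
    dominance: int = 40,
) -> PFM:
    """A random but realistic PFM: each position gets a dominant base with
    ~`dominance` counts over a small Dirichlet-ish remainder, giving the
    sharply conserved columns typical of curated motif libraries."""
    counts = rng.integers(0, 6, size=(length, 4)).astype(float)
    dominant = rng.integers(0, 4, size=length)
    counts[np.arange(length), dominant] += dominance + rng.integers(0, 10, size=length)
    if concentration > 0:  # soften a couple of positions so the core is non-trivial
        soft = rng.choice(length, size=max(1, length // 4), replace=False)
        counts[soft] += rng.integers(5, 15, size=(len(soft), 4))
    return PFM(id=tf_id, name=tf_id, counts=counts)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=probs)])


def random_genome_gtf(
    rng: np.random.Generator,
    n_chroms: int = 2,
    chrom_length: int = 20_000,
    n_genes: int = 8,
    gc: float = 0.45,
) -> tuple[dict[str, str], str]:
    """A toy genome plus a matching Ensembl-style GTF with transcript features.

    Genes alternate strand and are spaced so default promoter windows stay
    inside the contig; some genes get two transcripts with distinct TSSs.
    """
    genome = {
        f"chr{c + 1}": _random_seq(rng, chrom_length, gc) for c in range(n_chroms)
    }
    lines: list[str] = []
    for g in range(n_genes):
        chrom = f"chr{(g % n_chroms) + 1}"
        strand = "+" if g % 2 == 0 else "-"
        anchor = 3000 + (g // n_chroms) * 4000
        gene_id = f"ENSTEST{g + 1:011d}"
        symbol = f"GENE{g + 1}"
        n_tx = 2 if g % 3 == 0 else 1
        for t in range(n_tx):
            tx_id = f"ENSTESTT{g + 1:08d}{t + 1:02d}"
            shift = t * int(rng.integers(50, 300))
            if strand == "+":
                start, end = anchor + shift, anchor + shift + 1200
            else:
                end = anchor + 1200 - shift
                start = end - 1200
            attrs = (
                f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                f'gene_name "{symbol}";'
            )
            lines.append(
                f"{chrom}\ttest\ttranscript\t{start + 1}\t{end + 1}\t.\t{strand}\t.\t{attrs}"
            )
    return genome, "\n".join(lines) + "\n"


def make_fixture(spec: FixtureSpec = FixtureSpec()) -> Fixture:
    """Generate a planted-motif benchmark: query/background sequences, a PFM
    library (planted TFs + decoys), scoring models and a truth table.

    Each planted instance is the exact consensus of its matrix, inserted at a
    random position on a random strand; overlaps between plantings in one
    sequence are avoided greedily. Decoy TFs are never planted.
    """
    rng = np.random.default_rng(spec.seed)
    pfms: list[PFM] = []
    for tf_id, _, _ in spec.planted:
        pfms.append(random_pfm(rng, tf_id, spec.motif_length))
    for d in range(spec.n_decoy_tfs):
        pfms.append(random_pfm(rng, f"TF_DECOY{d + 1}", spec.motif_length))
    models = [build_scoring_model(p) for p in pfms]
    consensus = {m.id: m.consensus for m in models}

    truth_rows: list[dict] = []

    def build_set(set_name: str, n: int, rate_index: int) -> list[SequenceRecord]:
        out: list[SequenceRecord] = []
        for i in range(n):
            sid = f"{set_name}_{i + 1}"
            seq = list(_random_seq(rng, spec.seq_length, spec.gc_content))
            occupied: list[tuple[int, int]] = []
            for tf_id, qr, br in spec.planted:
                rate = (qr, br)[rate_index]
                if rng.random() >= rate:
                    continue
                motif = consensus[tf_id]
                L = len(motif)
                for _attempt in range(50):
                    pos = int(rng.integers(0, spec.seq_length - L + 1))
                    if all(pos + L <= s or pos >= e for s, e in occupied):
                        break
                else:
                    continue
                occupied.append((pos, pos + L))
                strand = "+" if rng.random() < 0.5 else "-"
                inserted = motif if strand == "+" else reverse_complement(motif)
                seq[pos : pos + L] = inserted
                truth_rows.append(
                    {"set": set_name, "seq_id": sid, "tf_id": tf_id,
                     "start": pos, "end": pos + L, "strand": strand}
                )
            out.append(SequenceRecord(id=sid, description=sid, seq="".join(seq)))
        return out

    query = build_set("query", spec.n_query, 0)
    background = build_set("background", spec.n_background, 1)
    truth = pd.DataFrame(
        truth_rows, columns=["set", "seq_id", "tf_id", "start", "end", "strand"]
    )
    return Fixture(query=query, background=background, pfms=pfms, models=models, truth=truth)
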