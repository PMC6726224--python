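"""Two-stage TFBS scan with the information-weighted MATCH similarity score.

A window of length L scores

    score = (Current - Min) / (Max - Min),   Current = Σ_i I(i)·f(i, b_i)

where f are the matrix frequencies, I the information vector, and Min/Max
the information-weighted bounds over the worst/best base at each position.
The score lies in [0, 1]; the consensus sequence scores exactly 1.

Scanning is two-stage: the five-base core (most conserved window of the
matrix) slides along the sequence first; wherever the core similarity
reaches the acceptance threshold, the single full-length window whose core
aligns with that 5-mer is scored, and kept if it also reaches the
threshold. The threshold is 1 - deficit (default deficit 0.15, i.e. accept
scores >= 0.85; the same cut-off applies to core and matrix scores). The
prefilter is an optimisation only: it cannot lose a hit whose core passes.

Both strands are scanned by default; minus-strand hits are reported in
forward-strand coordinates of the scanned sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrices import CORE_WIDTH, ScoringModel
from .sequences import SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

__all__ = ["ScanConfig", "SiteHit", "match_score", "scan_sequence", "scan_set",
           "hits_to_frame", "write_site_table", "site_table_to_bed"]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

SITE_COLUMNS = ["seq_id", "tf_id", "tf_name", "start", "end", "strand",
                "core_score", "matrix_score"]


@dataclass(frozen=True)
class ScanConfig:
    """Scan stringency and strand/ambiguity policy.

    deficit: 1 minus the minimum accepted similarity score, in [0, 1).
    strands: "both" (default) or "forward".
    n_policy: "reject_window" discards any window containing N (default);
        "zero_weight" lets N contribute each position's minimum frequency.
    """

    deficit: float = 0.15
    strands: str = "both"
    n_policy: str = "reject_window"

    def __post_init__(self) -> None:
        if not 0.0 <= self.deficit < 1.0:
            raise ValueError("deficit must be in [0, 1)")
        if self.strands not in ("both", "forward"):
            raise ValueError("strands must be 'both' or 'forward'")
        if self.n_policy not in ("reject_window", "zero_weight"):
            raise ValueError("n_policy must be 'reject_window' or 'zero_weight'")

    @property
    def threshold(self) -> float:
        return 1.0 - self.deficit


@dataclass(frozen=True)
class SiteHit:
    """One predicted binding site, 0-based half-open on the forward strand."""

    seq_id: str
    tf_id: str
    tf_name: str
    start: int
    end: int
    strand: str
    core_score: float
    matrix_score: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


_CODE_LUT = np.full(128, 4, dtype=np.int8)
for _b, _c in _BASE_CODE.items():
    _CODE_LUT[ord(_b)] = _c


def _weight_table(model: ScoringModel, n_policy: str) -> np.ndarray:
    """(L, 5) table of I(i)·f(i, b) with column 4 = the N policy weight."""
    W = model.fm.info[:, None] * model.fm.freqs  # (L, 4)
    if n_policy == "zero_weight":
        ncol = W.min(axis=1, keepdims=True)
    else:
        ncol = np.full((W.shape[0], 1), -np.inf)  # poisons any window with N
    return np.hstack([W, ncol])


def match_score(model: ScoringModel, window: str) -> float:
    """Similarity score of one window against the full matrix (len L) or the
    core alone (len 5). Raises on any other length or on non-ACGT characters."""
    L = len(model)
    codes = _CODE_LUT[_encode(window.upper())]
    if (codes == 4).any():
        raise ValueError("window must contain only A/C/G/T")
    W = model.fm.info[:, None] * model.fm.freqs
    core = model.core
    if len(window) == L:
        current = W[np.arange(L), codes].sum()
        lo, hi = core.matrix_min, core.matrix_max
    elif len(window) == CORE_WIDTH:
        sl = np.arange(core.offset, core.offset + CORE_WIDTH)
        current = W[sl, codes].sum()
        lo, hi = core.core_min, core.core_max
    else:
        raise ValueError(
            f"window length {len(window)} matches neither matrix ({L}) nor core ({CORE_WIDTH})"
        )
    return float((current - lo) / (hi - lo))


def _scan_codes(
    codes: np.ndarray, model: ScoringModel, cfg: ScanConfig
) -> list[tuple[int, float, float]]:
    """Hits on one strand of an encoded sequence: (start, core_score, matrix_score)."""
    L = len(model)
    n = codes.shape[0]
    if n < L:
        return []
    W = _weight_table(model, cfg.n_policy)
    core = model.core
    o = core.offset

    # stage 1: core similarity at every 5-mer start
    core_W = W[o : o + CORE_WIDTH]
    kmers = np.lib.stride_tricks.sliding_window_view(codes, CORE_WIDTH)
    core_cur = core_W[np.arange(CORE_WIDTH), kmers].sum(axis=1)
    core_scores = (core_cur - core.core_min) / (core.core_max - core.core_min)
    # full window must fit: core 5-mer at p implies matrix window at p - o
    p = np.nonzero(core_scores >= cfg.threshold - 1e-12)[0]
    p = p[(p >= o) & (p - o + L <= n)]
    if p.size == 0:
        return []

    # stage 2: full-matrix similarity for surviving windows
    starts = p - o
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)[starts]
    cur = W[np.arange(L), windows].sum(axis=1)
    scores = (cur - core.matrix_min) / (core.matrix_max - core.matrix_min)
    keep = scores >= cfg.threshold - 1e-12
    return [
        (int(s), float(cs), float(ms))
        for s, cs, ms in zip(starts[keep], core_scores[p][keep], scores[keep])
    ]


def scan_sequence(
    seq: SequenceRecord, model: ScoringModel, cfg: ScanConfig = ScanConfig()
) -> list[SiteHit]:
    """All accepted sites of one TF model in one sequence.

    Output is sorted by (start, strand); minus-strand hits (found by scanning
    the reverse complement) are mapped back to forward-strand coordinates.
    A palindromic site passing on both strands is reported once per strand.
    """
    n = len(seq.seq)
    L = len(model)
    codes = _CODE_LUT[_encode(seq.seq)]
    hits: list[SiteHit] = []
    for start, cs, ms in _scan_codes(codes, model, cfg):
        hits.append(SiteHit(seq.id, model.id, model.name, start, start + L, "+", cs, ms))
    if cfg.strands == "both":
        rc = _CODE_LUT[_encode(reverse_complement(seq.seq))]
        for start, cs, ms in _scan_codes(rc, model, cfg):
            fwd_start = n - (start + L)
            hits.append(
                SiteHit(seq.id, model.id, model.name, fwd_start, fwd_start + L, "-", cs, ms)
            )
    hits.sort(key=lambda h: (h.start, h.tf_id, h.strand))
    return hits


def scan_set(
    seqs: Sequence[SequenceRecord],
    models: Sequence[ScoringModel],
    cfg: ScanConfig = ScanConfig(),
    per_model_deficit: Mapping[str, float] | None = None,
) -> list[SiteHit]:
    """Scan every sequence against every model; deterministic order.

    `per_model_deficit` optionally overrides the global deficit per tf_id.
    """
    if not seqs:
        raise ValueError("no sequences to scan")
    if not models:
        raise ValueError("no matrix models to scan with")
    hits: list[SiteHit] = []
    for model in models:
        mcfg = cfg
        if per_model_deficit and model.id in per_model_deficit:
            mcfg = ScanConfig(per_model_deficit[model.id], cfg.strands, cfg.n_policy)
        count = 0
        for seq in seqs:
            h = scan_sequence(seq, model, mcfg)
            count += len(h)
            hits.extend(h)
        logger.info("%s: %d hit(s) across %d sequence(s)", model.id, count, len(seqs))
    hits.sort(key=lambda h: (h.seq_id, h.start, h.tf_id, h.strand))
    return hits


def hits_to_frame(hits: Iterable[SiteHit]) -> pd.DataFrame:
    """Site table as a DataFrame with the standard column order."""
    return pd.DataFrame([h.__dict__ for h in hits], columns=SITE_COLUMNS)


def write_site_table(hits: Iterable[SiteHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def site_table_to_bed(hits: Iterable[SiteHit], path: str | Path) -> None:
    """BED6 export: score column = round(1000 * matrix_score)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.tf_id}\t"
                f"{round(1000 * h.matrix_score)}\t{h.strand}\n"
            )
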