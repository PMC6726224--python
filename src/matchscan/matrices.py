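"""Position frequency matrices: parsing, normalisation, information content, core selection.

A PFM summarises experimentally observed binding sequences as per-position
nucleotide counts. Scoring needs frequencies, a per-position conservation
measure (the information vector) and, for the two-stage scan, the five
consecutive positions of maximal summed information — the *core*.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
CORE_WIDTH = 5

__all__ = [
    "PFM",
    "FrequencyMatrix",
    "CoreModel",
    "PFMParseError",
    "parse_jaspar",
    "parse_transfac",
    "to_frequency",
    "information_vector",
    "select_core",
    "ScoringModel",
    "build_scoring_model",
]


class PFMParseError(ValueError):
    """Raised when a matrix record cannot be parsed or fails validation."""


@dataclass
class PFM:
    """Position frequency matrix: ``counts[i, b]`` with b indexing A,C,G,T.

    Matrices shorter than five positions are rejected at parse time because
    the scan's core model needs a five-base window.
    """

    id: str
    name: str
    counts: np.ndarray  # (L, 4) float, non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise PFMParseError(f"{self.id}: counts must be L x 4")
        if not np.isfinite(self.counts).all() or (self.counts < 0).any():
            raise PFMParseError(f"{self.id}: counts must be finite and >= 0")
        if len(self) < CORE_WIDTH:
            raise PFMParseError(
                f"{self.id}: matrix length {len(self)} < {CORE_WIDTH} (too short for a core)"
            )
        if (self.counts.sum(axis=1) <= 0).any():
            raise PFMParseError(f"{self.id}: every position needs a positive column sum")

    def __len__(self) -> int:
        return self.counts.shape[0]


@dataclass
class FrequencyMatrix:
    """Smoothed per-position base frequencies plus their information vector."""

    freqs: np.ndarray  # (L, 4), rows sum to 1
    info: np.ndarray  # (L,), non-negative
    pseudocount: float

    def __len__(self) -> int:
        return self.freqs.shape[0]


@dataclass
class CoreModel:
    """Location of the five most conserved consecutive positions and the
    information-weighted score bounds used to normalise MATCH scores."""

    offset: int
    width: int
    core_min: float
    core_max: float
    matrix_min: float
    matrix_max: float


@dataclass
class ScoringModel:
    """Everything the scanner needs for one TF: identity, frequencies, core."""

    id: str
    name: str
    fm: FrequencyMatrix
    core: CoreModel

    def __len__(self) -> int:
        return len(self.fm)

    @property
    def consensus(self) -> str:
        """Highest-frequency base at each position (ties broken A<C<G<T)."""
        return "".join(ALPHABET[b] for b in np.argmax(self.fm.freqs, axis=1))


# ---------------------------------------------------------------------------
# parsing


def _finish_record(header: str, rows: dict[str, list[float]]) -> PFM:
    ident = header.lstrip(">").strip()
    parts = ident.split(None, 1)
    mat_id = parts[0] if parts else ident
    name = parts[1].strip() if len(parts) > 1 else mat_id
    missing = [b for b in ALPHABET if b not in rows]
    if missing:
        raise PFMParseError(f"{mat_id}: missing nucleotide row(s) {','.join(missing)}")
    lengths = {len(rows[b]) for b in ALPHABET}
    if len(lengths) != 1:
        raise PFMParseError(f"{mat_id}: unequal row lengths {sorted(lengths)}")
    counts = np.array([rows[b] for b in ALPHABET], dtype=float).T
    return PFM(id=mat_id, name=name, counts=counts)


_JASPAR_ROW = re.compile(r"^\s*([ACGTacgt])\s*[\[\|:]?\s*(.*?)\s*\]?\s*$")


def parse_jaspar(text: str) -> list[PFM]:
    """Parse JASPAR-format matrix text into a list of PFMs.

    Accepts both the bracketed dialect (``A  [ 3 5 ... ]``) and plain
    whitespace-separated count rows. Records shorter than five positions are
    skipped with a warning rather than aborting the whole library.
    """
    pfms: list[PFM] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        try:
            pfms.append(_finish_record(header, rows))
        except PFMParseError as exc:
            if "too short for a core" in str(exc):
                logger.warning("skipping matrix: %s", exc)
            else:
                raise
        header, rows = None, {}

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line
            continue
        if header is None:
            raise PFMParseError(f"count row before any '>' header: {line!r}")
        m = _JASPAR_ROW.match(line)
        if not m:
            raise PFMParseError(f"{header}: unparseable row {line!r}")
        base = m.group(1).upper()
        try:
            values = [float(tok) for tok in m.group(2).split()]
        except ValueError as exc:
            raise PFMParseError(f"{header}: bad count in row {line!r}") from exc
        if base in rows:
            raise PFMParseError(f"{header}: duplicate {base} row")
        rows[base] = values
    flush()
    if not pfms and header is None:
        raise PFMParseError("no matrix records found")
    return pfms


def parse_transfac(text: str) -> list[PFM]:
    """Parse TRANSFAC flat-file matrix blocks (AC/ID/PO..//).

    The consensus column after the four counts, if present, is ignored.
    Matrices shorter than five positions are skipped with a warning.
    """
    pfms: list[PFM] = []
    blocks = [b for b in text.split("//") if b.strip()]
    for block in blocks:
        ac = ident = None
        order: list[int] | None = None
        position_rows: list[list[float]] = []
        for line in block.splitlines():
            line = line.rstrip()
            if not line.strip():
                continue
            tag, _, rest = line.partition("  ")
            tag = line[:2]
            rest = line[2:].strip()
            if tag == "AC":
                ac = rest
            elif tag == "ID":
                ident = rest
            elif tag in ("PO", "P0"):
                cols = rest.split()
                try:
                    order = [cols.index(b) for b in ALPHABET]
                except ValueError as exc:
                    raise PFMParseError(
                        f"{ac or '<no AC>'}: PO line must name A C G T, got {rest!r}"
                    ) from exc
            elif tag[:2].isdigit() or (tag[0].isdigit() and tag[1] == " "):
                if order is None:
                    raise PFMParseError(f"{ac or '<no AC>'}: position row before PO/P0 header")
                fields = rest.split()
                if len(fields) < 4:
                    raise PFMParseError(f"{ac or '<no AC>'}: truncated position row {line!r}")
                try:
                    vals = [float(fields[j]) for j in order]
                except ValueError as exc:
                    raise PFMParseError(f"{ac or '<no AC>'}: bad count in {line!r}") from exc
                position_rows.append(vals)
        if not position_rows:
            if ac or ident:
                raise PFMParseError(f"{ac or ident}: block has no position rows")
            continue
        if order is None:
            raise PFMParseError(f"{ac or '<no AC>'}: missing PO/P0 header")
        mat_id = ac or ident or f"MATRIX{len(pfms) + 1}"
        name = ident or mat_id
        try:
            pfms.append(PFM(id=mat_id, name=name, counts=np.array(position_rows)))
        except PFMParseError as exc:
            if "too short for a core" in str(exc):
                logger.warning("skipping matrix: %s", exc)
            else:
                raise
    if not pfms and not blocks:
        raise PFMParseError("no matrix blocks found")
    return pfms


# ---------------------------------------------------------------------------
# frequencies, information, core

#: Default total pseudocount spread evenly over the four bases. Keeps log
#: terms finite for zero counts while barely perturbing well-sampled columns.
DEFAULT_PSEUDOCOUNT = 0.8


def to_frequency(pfm: PFM, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> FrequencyMatrix:
    """Convert counts to smoothed frequencies and attach the information vector.

    freqs[i, B] = (counts[i, B] + pseudocount) / (rowsum_i + 4·pseudocount);
    the same pseudocount goes to each base, so a uniform row stays uniform.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (pfm.counts == 0).any():
        raise ValueError(
            f"{pfm.id}: zero counts require a positive pseudocount (log(0) downstream)"
        )
    totals = pfm.counts.sum(axis=1, keepdims=True)
    freqs = (pfm.counts + pseudocount) / (totals + 4 * pseudocount)
    return FrequencyMatrix(freqs=freqs, info=information_vector(freqs), pseudocount=pseudocount)


def information_vector(freqs: np.ndarray) -> np.ndarray:
    """Per-position conservation I(i) = Σ_B f(i,B)·ln(4·f(i,B)).

    Zero for a uniform position, ln 4 in the limit of an invariant one.
    Natural log throughout; the base only rescales the weights and cancels
    in the normalised similarity score.
    """
    freqs = np.asarray(freqs, dtype=float)
    if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("frequency rows must sum to 1")
    if (freqs <= 0).any():
        raise ValueError("frequencies must be strictly positive (apply a pseudocount)")
    info = np.einsum("ij,ij->i", freqs, np.log(4.0 * freqs))
    # floating-point noise can leave tiny negatives on uniform rows
    return np.maximum(info, 0.0)


def select_core(fm: FrequencyMatrix) -> CoreModel:
    """Pick the five consecutive positions with maximal summed information.

    Ties go to the leftmost (5'-most) window. Also computes the
    information-weighted score bounds for the core window and the full
    matrix: min = Σ I(i)·min_B f(i,B), max = Σ I(i)·max_B f(i,B).
    """
    L = len(fm)
    if L < CORE_WIDTH:
        raise ValueError(f"matrix length {L} < core width {CORE_WIDTH}")
    window_sums = np.convolve(fm.info, np.ones(CORE_WIDTH), mode="valid")
    offset = int(np.argmax(window_sums))  # argmax returns first maximum: leftmost tie-break

    wmin = fm.info * fm.freqs.min(axis=1)
    wmax = fm.info * fm.freqs.max(axis=1)
    sl = slice(offset, offset + CORE_WIDTH)
    return CoreModel(
        offset=offset,
        width=CORE_WIDTH,
        core_min=float(wmin[sl].sum()),
        core_max=float(wmax[sl].sum()),
        matrix_min=float(wmin.sum()),
        matrix_max=float(wmax.sum()),
    )


def build_scoring_model(pfm: PFM, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ScoringModel:
    """Bundle frequencies + core for the scanner; rejects fully uniform matrices."""
    fm = to_frequency(pfm, pseudocount)
    core = select_core(fm)
    if core.matrix_max <= core.matrix_min or core.core_max <= core.core_min:
        raise ValueError(
            f"{pfm.id}: matrix is fully uniform — no score range, refusing to scan"
        )
    return ScoringModel(id=pfm.id, name=pfm.name, fm=fm, core=core)
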