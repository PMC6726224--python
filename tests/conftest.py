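"""Shared fixtures and independent oracles.

The oracles here re-derive scores and p-values from first principles
(per-window arithmetic in pure Python, full hypergeometric enumeration) so
the package's vectorised / library-backed paths are checked against an
implementation that shares none of their code.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from matchscan import ScanConfig, ScoringModel, SequenceRecord
from matchscan.matrices import PFM, build_scoring_model
from matchscan.sequences import reverse_complement

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

JASPAR_TEXT = """\
>MA0001.1 TFA
A [ 10  2  0  0  8  1 ]
C [  0  1 10  0  1  2 ]
G [  0  7  0  0  1  6 ]
T [  0  0  0 10  0  1 ]
>MA0002.1 TFB
T 0 0 9 1 0
G 9 0 0 1 0
C 1 0 1 8 0
A 0 10 0 0 10
"""

TRANSFAC_TEXT = """\
AC M00001
XX
ID V$TFA_01
XX
PO      A      C      G      T
01      10      0      0      0
02      0      8      1      1
03      0      0      10      0
04      1      0      0      9
05      9      0      1      0
06      2      2      4      2
XX
//
AC M00002
ID V$TFB_01
P0      A      C      G      T
01      0      0      0      10
02      10      0      0      0
03      0      10      0      0
04      0      0      10      0
05      5      5      0      0
//
"""


def oracle_window_score(model: ScoringModel, window: str, part: str) -> float:
    """First-principles MATCH score of one window, pure Python.

    part = "matrix" scores the full-length window; part = "core" scores a
    5-base window against the core positions.
    """
    freqs, info, core = model.fm.freqs, model.fm.info, model.core
    if part == "matrix":
        positions = range(len(model))
        lo, hi = core.matrix_min, core.matrix_max
    else:
        positions = range(core.offset, core.offset + core.width)
        lo, hi = core.core_min, core.core_max
    current = 0.0
    for k, i in enumerate(positions):
        current += info[i] * freqs[i, BASE_INDEX[window[k]]]
    return (current - lo) / (hi - lo)


def oracle_scan(seq: SequenceRecord, model: ScoringModel, cfg: ScanConfig):
    """Exhaustive all-windows scan with no core prefilter.

    Every full window whose core sub-window and full score both reach the
    threshold is a hit; both strands; minus-strand in forward coordinates.
    Returns a set of (start, strand, round(core), round(matrix)) tuples.
    """
    L = len(model)
    o, w = model.core.offset, model.core.width
    results = set()
    for strand, s in (("+", seq.seq), ("-", reverse_complement(seq.seq))):
        n = len(s)
        for start in range(n - L + 1):
            window = s[start : start + L]
            if "N" in window:
                if cfg.n_policy == "reject_window":
                    continue
                raise NotImplementedError("oracle only covers reject_window")
            cs = oracle_window_score(model, window[o : o + w], "core")
            if cs < cfg.threshold - 1e-12:
                continue
            ms = oracle_window_score(model, window, "matrix")
            if ms < cfg.threshold - 1e-12:
                continue
            fwd = start if strand == "+" else n - start - L
            results.add((fwd, strand, round(cs, 9), round(ms, 9)))
    return results


def oracle_fisher(n_s: int, N_s: int, n_b: int, N_b: int) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins.

    Hypergeometric probabilities computed from binomial coefficients with
    exact integer arithmetic, summed over tables at most as probable as the
    one observed (probability-mass rule).
    """
    k = n_s + n_b
    total = math.comb(N_s + N_b, k)
    obs = math.comb(N_s, n_s) * math.comb(N_b, n_b)
    acc = 0
    for x in range(max(0, k - N_b), min(k, N_s) + 1):
        m = math.comb(N_s, x) * math.comb(N_b, k - x)
        if m <= obs:  # exact integers: no floating tie ambiguity
            acc += m
    return acc / total


def random_model(rng: np.random.Generator, length: int | None = None) -> ScoringModel:
    """A random informative matrix (not from matchscan.synthetic) for oracle tests."""
    L = int(length or rng.integers(5, 13))
    counts = rng.integers(0, 4, size=(L, 4)).astype(float)
    counts[np.arange(L), rng.integers(0, 4, size=L)] += rng.integers(8, 30, size=L)
    pfm = PFM(id=f"RND{rng.integers(1e6)}", name="random", counts=counts)
    return build_scoring_model(pfm)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def jaspar_text():
    return JASPAR_TEXT


@pytest.fixture
def transfac_text():
    return TRANSFAC_TEXT
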