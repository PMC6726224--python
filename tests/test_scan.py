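"""Scanner semantics: score formula, prefilter completeness, strand symmetry."""

import numpy as np
import pytest

from matchscan import (
    ScanConfig,
    SequenceRecord,
    match_score,
    parse_jaspar,
    build_scoring_model,
    reverse_complement,
    scan_sequence,
    scan_set,
)
from conftest import (
    JASPAR_TEXT,
    oracle_scan,
    oracle_window_score,
    random_dna,
    random_model,
)


def _model_a():
    return build_scoring_model(parse_jaspar(JASPAR_TEXT)[0])


def _hit_key(hits):
    return {(h.start, h.strand, round(h.core_score, 9), round(h.matrix_score, 9))
            for h in hits}


class TestMatchScore:
    def test_consensus_is_one_anticonsensus_zero(self, rng):
        for _ in range(20):
            m = random_model(rng)
            consensus = "".join("ACGT"[b] for b in np.argmax(m.fm.freqs, axis=1))
            anti = "".join("ACGT"[b] for b in np.argmin(m.fm.freqs, axis=1))
            assert match_score(m, consensus) == pytest.approx(1.0, abs=1e-12)
            assert match_score(m, anti) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_evaluation(self):
        m = _model_a()  # 6-position matrix
        window = "ACGTAC"
        assert match_score(m, window) == pytest.approx(
            oracle_window_score(m, window, "matrix"), rel=1e-12
        )
        core5 = window[m.core.offset : m.core.offset + 5] if len(window) >= m.core.offset + 5 else None
        got = match_score(m, "ACGTA")
        assert got == pytest.approx(oracle_window_score(m, "ACGTA", "core"), rel=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            match_score(_model_a(), "ACGT")


class TestScanSequence:
    def test_consensus_hit_at_start(self):
        m = _model_a()
        seq = SequenceRecord("s", "s", m.consensus)
        hits = scan_sequence(seq, m, ScanConfig(deficit=0.15))
        fwd = [h for h in hits if h.strand == "+"]
        assert fwd[0].start == 0 and fwd[0].matrix_score == pytest.approx(1.0, abs=1e-12)

    def test_revcomp_reported_on_minus_strand_same_interval(self):
        m = _model_a()
        pad = "TTTTTTTTTT"
        seq = SequenceRecord("s", "s", pad + reverse_complement(m.consensus) + pad)
        hits = scan_sequence(seq, m, ScanConfig(deficit=0.15))
        minus = [h for h in hits if h.strand == "-" and h.matrix_score > 1 - 1e-9]
        assert len(minus) == 1
        assert (minus[0].start, minus[0].end) == (10, 10 + len(m))

    def test_prefilter_equals_exhaustive_oracle(self, rng):
        """Planted-consensus sequences: the two-stage scan must equal a scan
        of every window with no core prefilter."""
        for _ in range(25):
            m = random_model(rng)
            seq_s = list(random_dna(rng, 1000))
            pos = 400
            seq_s[pos : pos + len(m)] = m.consensus
            seq = SequenceRecord("s", "s", "".join(seq_s))
            cfg = ScanConfig(deficit=0.15)
            assert _hit_key(scan_sequence(seq, m, cfg)) == oracle_scan(seq, m, cfg)

    def test_n_rejected_by_default(self):
        m = _model_a()
        broken = m.consensus[:2] + "N" + m.consensus[3:]
        hits = scan_sequence(SequenceRecord("s", "s", broken), m, ScanConfig())
        assert all(h.matrix_score < 2 for h in hits)  # no crash
        assert not [h for h in hits if h.strand == "+" and h.start == 0]

    def test_short_sequence_empty(self):
        assert scan_sequence(SequenceRecord("s", "s", "ACG"), _model_a()) == []

    def test_threshold_monotonicity(self, rng):
        m = random_model(rng)
        seq = SequenceRecord("s", "s", random_dna(rng, 2000))
        strict = _hit_key(scan_sequence(seq, m, ScanConfig(deficit=0.05)))
        loose = _hit_key(scan_sequence(seq, m, ScanConfig(deficit=0.30)))
        assert strict <= loose

    def test_strand_involution(self, rng):
        for _ in range(10):
            m = random_model(rng)
            s = random_dna(rng, 500)
            n = len(s)
            fwd_hits = scan_sequence(SequenceRecord("s", "s", s), m, ScanConfig())
            rc_hits = scan_sequence(
                SequenceRecord("s", "s", reverse_complement(s)), m, ScanConfig()
            )
            flip = {
                (n - h.end, {"+": "-", "-": "+"}[h.strand],
                 round(h.core_score, 9), round(h.matrix_score, 9))
                for h in rc_hits
            }
            assert _hit_key(fwd_hits) == flip


class TestScanSet:
    def test_planted_counts(self, rng):
        m = random_model(rng, length=10)
        seqs = []
        for i in range(3):
            s = list(random_dna(rng, 300))
            s[50 : 50 + len(m)] = m.consensus
            seqs.append(SequenceRecord(f"s{i}", "", "".join(s)))
        hits = scan_set(seqs, [m], ScanConfig(deficit=0.15))
        exact = [h for h in hits if h.matrix_score > 1 - 1e-9 and h.strand == "+"]
        assert len(exact) == 3

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            scan_set([], [_model_a()])
        with pytest.raises(ValueError):
            scan_set([SequenceRecord("s", "", "ACGTACGT")], [])

    def test_scores_within_accepted_band(self, rng):
        m = random_model(rng)
        seq = SequenceRecord("s", "s", random_dna(rng, 3000))
        cfg = ScanConfig(deficit=0.25)
        for h in scan_sequence(seq, m, cfg):
            assert cfg.threshold - 1e-9 <= h.core_score <= 1 + 1e-12
            assert cfg.threshold - 1e-9 <= h.matrix_score <= 1 + 1e-12

    def test_per_model_deficit_override(self, rng):
        m = random_model(rng)
        seq = SequenceRecord("s", "s", random_dna(rng, 2000))
        loose = scan_set([seq], [m], ScanConfig(deficit=0.05),
                         per_model_deficit={m.id: 0.35})
        base = scan_set([seq], [m], ScanConfig(deficit=0.35))
        assert _hit_key(loose) == _hit_key(base)
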