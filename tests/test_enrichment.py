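"""Contingency counting, exact tests and the three enrichment statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from matchscan import (
    ContingencyCounts,
    SiteHit,
    count_bound,
    enrichment_stats,
    enrichment_to_frame,
    fisher_exact,
    mann_whitney,
    run_enrichment,
    sites_per_sequence,
)
from conftest import oracle_fisher


def _hit(seq_id, tf_id="TFX", strand="+", start=0):
    return SiteHit(seq_id, tf_id, tf_id, start, start + 10, strand, 0.9, 0.9)


class TestCountBound:
    def test_multiplicity_and_strand_collapse(self):
        hits = [_hit("s1"), _hit("s1", start=20), _hit("s1", strand="-")]
        assert count_bound(hits, ["s1", "s2"]) == {"TFX": 1}

    def test_zero_hit_tf_still_listed(self):
        assert count_bound([], ["s1"], tf_ids=["TFY"]) == {"TFY": 0}

    def test_membership(self):
        hits = [_hit(f"s{i}") for i in (1, 2, 5)]
        assert count_bound(hits, [f"s{i}" for i in range(1, 11)]) == {"TFX": 3}
        with pytest.raises(ValueError, match="unknown sequence"):
            count_bound([_hit("nope")], ["s1"])


class TestFisher:
    def test_identical_proportions_p_one(self):
        assert fisher_exact(ContingencyCounts("t", 5, 10, 5, 10)) == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        # all query bound, no background bound: only 2 equally-probable extreme tables
        p = fisher_exact(ContingencyCounts("t", 10, 10, 0, 10))
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert p == pytest.approx(1.0825e-5, rel=1e-3)

    @pytest.mark.parametrize("ns,Ns,nb,Nb", [(8, 10, 2, 10), (3, 7, 6, 9), (0, 5, 5, 5)])
    def test_matches_enumeration_oracle(self, ns, Ns, nb, Nb):
        got = fisher_exact(ContingencyCounts("t", ns, Ns, nb, Nb))
        assert got == pytest.approx(oracle_fisher(ns, Ns, nb, Nb), rel=1e-10)


class TestMannWhitney:
    def test_identical_lists(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]) >= 0.99

    def test_exact_matches_permutation_enumeration(self):
        # [3,4,5] vs [0,0,0]: all C(6,3)=20 assignments enumerable by hand;
        # the observed split is one of the 2 most extreme -> p = 2/20
        assert mann_whitney([3, 4, 5], [0, 0, 0]) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize(
        "x,y",
        [([0, 1, 1, 2], [2, 3, 3]), ([0, 0, 0, 5], [1, 1, 2, 2]), ([4, 6], [1, 2, 3])],
    )
    def test_exact_matches_scipy_permutation_test(self, x, y):
        def statistic(a, b):
            n1 = len(a)
            ranks = stats.rankdata(np.concatenate([a, b]))
            return abs(ranks[:n1].sum() - n1 * (n1 + 1) / 2 - n1 * len(b) / 2)

        ref = stats.permutation_test(
            (np.array(x, float), np.array(y, float)),
            statistic,
            permutation_type="independent",
            alternative="greater",
            n_resamples=np.inf,
        )
        assert mann_whitney(x, y) == pytest.approx(ref.pvalue, abs=1e-9)

    def test_large_sample_null_uniformish(self, rng):
        """Replicate p-values under the null should look U(0,1): KS not
        rejected at alpha = 0.01."""
        pvals = []
        for _ in range(1000):
            x = rng.poisson(2.0, size=30)
            y = rng.poisson(2.0, size=30)
            pvals.append(mann_whitney(x, y))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1])


class TestEnrichmentStats:
    def test_full_proportions_all_zero(self):
        avg, enr, sig = enrichment_stats(ContingencyCounts("t", 10, 10, 10, 10), 0.5)
        assert avg == pytest.approx(0.0)
        assert enr == 0.0 and sig == 0.0

    def test_printed_formulas(self):
        c = ContingencyCounts("t", 8, 10, 2, 10)
        avg, enr, sig = enrichment_stats(c, 0.001)
        assert enr == pytest.approx(math.log2(8.5 / 2.5), rel=1e-12)
        assert enr == pytest.approx(1.7655, abs=1e-4)
        assert avg == pytest.approx(
            0.5 * math.log2(8.5 / 10.5) + 0.5 * math.log2(2.5 / 10.5), rel=1e-12
        )
        assert sig == pytest.approx(3.0)  # over-represented at p=1e-3 -> +3

    def test_under_representation_negative_score(self):
        _, enr, sig = enrichment_stats(ContingencyCounts("t", 1, 10, 9, 10), 0.01)
        assert enr < 0 and sig == pytest.approx(-2.0)


class TestRunEnrichment:
    def _sets(self):
        qu = [f"q{i}" for i in range(10)]
        bu = [f"b{i}" for i in range(10)]
        qh = [_hit(s, "TFX") for s in qu[:8]]
        bh = [_hit(s, "TFX") for s in bu[:2]]
        return qh, qu, bh, bu

    def test_absent_tf_neutral_row(self):
        qh, qu, bh, bu = self._sets()
        rows = run_enrichment(qh, qu, bh, bu, tf_names={"TFX": "X", "TFZ": "Z"})
        z = next(r for r in rows if r.tf_id == "TFZ")
        assert z.fisher_p == 1.0 and z.log2_enrichment == 0.0 and z.significance_score == 0.0

    def test_swap_antisymmetry(self):
        qh, qu, bh, bu = self._sets()
        fwd = run_enrichment(qh, qu, bh, bu)[0]
        rev = run_enrichment(bh, bu, qh, qu)[0]
        assert rev.log2_enrichment == pytest.approx(-fwd.log2_enrichment, rel=1e-12)
        assert rev.significance_score == pytest.approx(-fwd.significance_score, rel=1e-12)
        assert rev.fisher_p == pytest.approx(fwd.fisher_p, rel=1e-12)

    def test_mismatched_deficits_rejected(self):
        qh, qu, bh, bu = self._sets()
        with pytest.raises(ValueError, match="different deficits"):
            run_enrichment(qh, qu, bh, bu, query_deficit=0.15, background_deficit=0.2)

    def test_mwu_and_fdr_columns(self):
        qh, qu, bh, bu = self._sets()
        rows = run_enrichment(qh, qu, bh, bu, tf_names={"TFX": "X", "TFZ": "Z"},
                              with_mwu=True, with_fdr=True)
        df = enrichment_to_frame(rows)
        assert "fisher_p_bh" in df.columns
        assert df["mwu_p"].notna().all()
        # BH on sorted p-values never decreases and never drops below raw p
        assert (df["fisher_p_bh"] >= df["fisher_p"] - 1e-12).all()

    def test_sites_per_sequence_includes_zeros(self):
        qh, qu, _, _ = self._sets()
        per = sites_per_sequence(qh, qu)["TFX"]
        assert sum(per.values()) == 8 and len(per) == 10
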