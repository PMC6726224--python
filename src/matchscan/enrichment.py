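"""Query-vs-background TFBS enrichment.

For each TF model the number of *sequences* with at least one predicted
site (hit multiplicity and strand do not matter) is tabulated in the query
and background sets, giving a 2x2 table (bound / unbound x query /
background) tested with Fisher's exact test. Optionally the full
sites-per-sequence distributions are compared with a Mann-Whitney U test.

Three summary statistics, with half-count continuity corrections so all
logarithms stay finite:

    avg_log2_prop_bound = 1/2·log2((n_S+1/2)/(N_S+1/2)) + 1/2·log2((n_B+1/2)/(N_B+1/2))
    log2_enrichment     = log2((n_S+1/2)/(N_S+1/2)) - log2((n_B+1/2)/(N_B+1/2))
    significance_score  = -sign(log2_enrichment) · log10(p)

The significance score is positive for over-represented TFs, negative for
under-represented ones, and zero when the enrichment is exactly zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scan import SiteHit

__all__ = [
    "ContingencyCounts",
    "EnrichmentRow",
    "count_bound",
    "sites_per_sequence",
    "fisher_exact",
    "mann_whitney",
    "enrichment_stats",
    "run_enrichment",
    "enrichment_to_frame",
    "write_enrichment_table",
]

#: Exact Mann-Whitney enumeration is used up to this combined sample size.
EXACT_MWU_LIMIT = 20

ENRICHMENT_COLUMNS = [
    "tf_id", "tf_name", "n_s", "N_s", "n_b", "N_b",
    "proportion_query", "proportion_background",
    "avg_log2_prop_bound", "log2_enrichment",
    "fisher_p", "mwu_p", "significance_score",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """Bound-sequence counts: n of N query / background sequences with >= 1 site."""

    tf_id: str
    n_s: int
    N_s: int
    n_b: int
    N_b: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_s <= self.N_s and 0 <= self.n_b <= self.N_b):
            raise ValueError(f"{self.tf_id}: counts out of range")
        if self.N_s < 1 or self.N_b < 1:
            raise ValueError(f"{self.tf_id}: need at least one sequence per set")


@dataclass(frozen=True)
class EnrichmentRow:
    tf_id: str
    tf_name: str
    counts: ContingencyCounts
    fisher_p: float
    mwu_p: float | None
    avg_log2_prop_bound: float
    log2_enrichment: float
    significance_score: float


def count_bound(
    hits: Iterable[SiteHit],
    universe: Sequence[str],
    tf_ids: Iterable[str] | None = None,
) -> dict[str, int]:
    """Per-TF count of sequences with >= 1 hit.

    Every hit's seq_id must be in `universe`. TFs listed in `tf_ids` appear
    in the result even with zero hits.
    """
    known = set(universe)
    if len(known) != len(universe):
        raise ValueError("universe contains duplicate sequence ids")
    bound: dict[str, set[str]] = {tf: set() for tf in (tf_ids or [])}
    for h in hits:
        if h.seq_id not in known:
            raise ValueError(f"hit references unknown sequence id {h.seq_id!r}")
        bound.setdefault(h.tf_id, set()).add(h.seq_id)
    return {tf: len(seqs) for tf, seqs in bound.items()}


def sites_per_sequence(
    hits: Iterable[SiteHit], universe: Sequence[str]
) -> dict[str, dict[str, int]]:
    """Per-TF mapping seq_id -> number of hits (zeros included for the universe)."""
    known = set(universe)
    out: dict[str, dict[str, int]] = {}
    for h in hits:
        if h.seq_id not in known:
            raise ValueError(f"hit references unknown sequence id {h.seq_id!r}")
        per = out.setdefault(h.tf_id, {s: 0 for s in universe})
        per[h.seq_id] += 1
    return out


def fisher_exact(c: ContingencyCounts) -> float:
    """Two-sided Fisher's exact p for the bound/unbound x query/background table.

    Two-sided by the probability-mass rule: the sum of hypergeometric
    probabilities of all tables with the observed margins that are at most
    as probable as the observed table.
    """
    table = [[c.n_s, c.N_s - c.n_s], [c.n_b, c.N_b - c.n_b]]
    p = stats.fisher_exact(table, alternative="two-sided").pvalue
    return float(min(p, 1.0))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y via midranks (ties shared)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def mann_whitney(
    query_counts: Sequence[int], background_counts: Sequence[int]
) -> float:
    """Two-sided Mann-Whitney U p comparing sites-per-sequence distributions.

    Exact permutation enumeration (tie-aware) when the combined sample size
    is at most 20; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(query_counts, dtype=float)
    y = np.asarray(background_counts, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both count lists must be non-empty")
    n1, n2 = x.size, y.size
    if n1 + n2 <= EXACT_MWU_LIMIT:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        mid = n1 * n2 / 2.0
        obs = abs(ranks[:n1].sum() - offset - mid)
        total = math.comb(n1 + n2, n1)
        hits = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mid) >= obs - 1e-9:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(min(res.pvalue, 1.0))


def enrichment_stats(
    c: ContingencyCounts, p: float
) -> tuple[float, float, float]:
    """The three summary statistics (see module docstring) for one TF."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    ls = math.log2((c.n_s + 0.5) / (c.N_s + 0.5))
    lb = math.log2((c.n_b + 0.5) / (c.N_b + 0.5))
    avg = 0.5 * ls + 0.5 * lb
    enr = ls - lb
    sign = (enr > 0) - (enr < 0)
    sig = -sign * math.log10(p)
    return avg, enr, sig


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, pvals[i] * m / (rank + 1))
        adj[i] = running
    return adj


def run_enrichment(
    query_hits: Iterable[SiteHit],
    query_universe: Sequence[str],
    background_hits: Iterable[SiteHit],
    background_universe: Sequence[str],
    tf_names: Mapping[str, str] | None = None,
    query_deficit: float | None = None,
    background_deficit: float | None = None,
    with_mwu: bool = False,
    with_fdr: bool = False,
) -> list[EnrichmentRow]:
    """Per-TF enrichment of the query set over the background set.

    Both sets must have been scanned with the same criteria; if the two
    deficits are supplied they are checked for equality. `tf_names` also
    fixes the set of TFs reported (zero-hit TFs get p = 1, enrichment 0).
    When `with_fdr` is set a `fisher_p_bh` attribute-column is added by
    `enrichment_to_frame`.
    """
    if (
        query_deficit is not None
        and background_deficit is not None
        and query_deficit != background_deficit
    ):
        raise ValueError(
            "query and background were scanned with different deficits "
            f"({query_deficit} vs {background_deficit}); criteria must match"
        )
    query_hits = list(query_hits)
    background_hits = list(background_hits)
    tf_ids = set(tf_names or [])
    tf_ids.update(h.tf_id for h in query_hits)
    tf_ids.update(h.tf_id for h in background_hits)
    names = dict(tf_names or {})
    for h in itertools.chain(query_hits, background_hits):
        names.setdefault(h.tf_id, h.tf_name)

    n_query = count_bound(query_hits, query_universe, tf_ids)
    n_background = count_bound(background_hits, background_universe, tf_ids)
    if with_mwu:
        spq = sites_per_sequence(query_hits, query_universe)
        spb = sites_per_sequence(background_hits, background_universe)

    rows: list[EnrichmentRow] = []
    for tf in sorted(tf_ids):
        c = ContingencyCounts(
            tf, n_query[tf], len(query_universe), n_background[tf], len(background_universe)
        )
        p = fisher_exact(c)
        avg, enr, sig = enrichment_stats(c, p)
        mwu_p = None
        if with_mwu:
            qc = list(spq.get(tf, {s: 0 for s in query_universe}).values())
            bc = list(spb.get(tf, {s: 0 for s in background_universe}).values())
            mwu_p = mann_whitney(qc, bc)
        rows.append(
            EnrichmentRow(tf, names.get(tf, tf), c, p, mwu_p, avg, enr, sig)
        )
    rows.sort(key=lambda r: (-r.significance_score, r.fisher_p, r.tf_id))
    if with_fdr:
        adj = _bh_adjust(np.array([r.fisher_p for r in rows]))
        for r, a in zip(rows, adj):
            object.__setattr__(r, "fisher_p_bh", float(a))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        c = r.counts
        rec = {
            "tf_id": r.tf_id,
            "tf_name": r.tf_name,
            "n_s": c.n_s,
            "N_s": c.N_s,
            "n_b": c.n_b,
            "N_b": c.N_b,
            "proportion_query": c.n_s / c.N_s,
            "proportion_background": c.n_b / c.N_b,
            "avg_log2_prop_bound": r.avg_log2_prop_bound,
            "log2_enrichment": r.log2_enrichment,
            "fisher_p": r.fisher_p,
            "mwu_p": r.mwu_p,
            "significance_score": r.significance_score,
        }
        if hasattr(r, "fisher_p_bh"):
            rec["fisher_p_bh"] = r.fisher_p_bh
        records.append(rec)
    cols = ENRICHMENT_COLUMNS + (
        ["fisher_p_bh"] if records and "fisher_p_bh" in records[0] else []
    )
    return pd.DataFrame(records, columns=cols)


def write_enrichment_table(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    enrichment_to_frame(rows).to_csv(path, sep="\t", index=False)
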