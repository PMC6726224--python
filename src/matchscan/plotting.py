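"""Static site-map figure: predicted binding sites drawn along their sequences.

One horizontal track per sequence, with each accepted site drawn as a
strand-marked glyph at its scaled position and a legend of the TFs shown
(by default the ten most significant). Display filters only hide glyphs;
they never alter the underlying site or enrichment tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.lines import Line2D

from .enrichment import EnrichmentRow
from .scan import SiteHit
from .sequences import SequenceRecord

__all__ = ["SiteMapSpec", "render_site_map"]

import logging

logger = logging.getLogger(__name__)

DEFAULT_TFS_SHOWN = 10


@dataclass
class SiteMapSpec:
    """Display-only options for the site map.

    tfs_shown: tf_ids to draw; None selects the top `DEFAULT_TFS_SHOWN` by
        significance score (falling back to hit count without enrichment rows).
    deficit_filter / p_filter: hide sites below 1 - deficit_filter similarity
        or TFs with Fisher p above p_filter.
    """

    tfs_shown: Sequence[str] | None = None
    deficit_filter: float = 1.0
    p_filter: float = 1.0
    sequence_order: Sequence[str] | None = None
    colours: Mapping[str, str] | None = None


def render_site_map(
    hits: Sequence[SiteHit],
    sequences: Sequence[SequenceRecord],
    path: str | Path,
    spec: SiteMapSpec = SiteMapSpec(),
    enrichment: Sequence[EnrichmentRow] | None = None,
) -> None:
    """Write a static SVG/PNG site map (format chosen by the path suffix)."""
    by_row = {r.tf_id: r for r in (enrichment or [])}

    shown = list(spec.tfs_shown) if spec.tfs_shown is not None else None
    if shown is None:
        if enrichment:
            ranked = sorted(
                by_row.values(), key=lambda r: (-abs(r.significance_score), r.fisher_p)
            )
            shown = [r.tf_id for r in ranked[:DEFAULT_TFS_SHOWN]]
        else:
            counts: dict[str, int] = {}
            for h in hits:
                counts[h.tf_id] = counts.get(h.tf_id, 0) + 1
            shown = sorted(counts, key=lambda t: (-counts[t], t))[:DEFAULT_TFS_SHOWN]

    threshold = 1.0 - spec.deficit_filter
    drawn = [
        h
        for h in hits
        if h.tf_id in shown
        and h.matrix_score >= threshold
        and (h.tf_id not in by_row or by_row[h.tf_id].fisher_p <= spec.p_filter)
    ]
    if not drawn:
        logger.info("site map: no sites pass the display filters; drawing empty tracks")

    order = list(spec.sequence_order) if spec.sequence_order else [s.id for s in sequences]
    lengths = {s.id: len(s.seq) for s in sequences}
    row_of = {sid: i for i, sid in enumerate(order)}

    cmap = plt.get_cmap("tab10")
    colour = {tf: cmap(i % 10) for i, tf in enumerate(shown)}
    if spec.colours:
        colour.update(spec.colours)

    fig, ax = plt.subplots(figsize=(10, max(2.0, 0.4 * len(order) + 1.2)))
    for sid in order:
        y = row_of[sid]
        ax.hlines(y, 0, lengths.get(sid, 0), color="0.8", lw=2, zorder=1)
    for h in drawn:
        if h.seq_id not in row_of:
            continue
        y = row_of[h.seq_id]
        marker = "^" if h.strand == "+" else "v"
        ax.scatter(
            (h.start + h.end) / 2, y, marker=marker, s=45,
            color=colour.get(h.tf_id, "0.3"), zorder=2,
        )
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=8)
    ax.invert_yaxis()
    ax.set_xlabel("position (bases)")
    ax.set_ylabel("")
    handles = [
        Line2D([], [], marker="s", linestyle="", color=colour[tf], label=tf)
        for tf in shown
    ]
    if handles:
        ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.01, 0.5),
                  fontsize=8, frameon=False)
    ax.spines[["top", "right"]].set_visible(False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
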