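"""Render a static site map: predicted sites drawn along their sequences.

Scans a small planted-motif fixture and writes an SVG with one track per
sequence; up/down triangles mark forward/minus-strand sites and the legend
lists the TFs shown (top ten by significance by default).
"""

from matchscan import (
    FixtureSpec, SiteMapSpec, make_fixture, render_site_map,
    run_enrichment, scan_set,
)

fx = make_fixture(FixtureSpec(seed=4, n_query=10, n_background=10, seq_length=300))
query_hits = scan_set(fx.query, fx.models)
background_hits = scan_set(fx.background, fx.models)
rows = run_enrichment(
    query_hits, [s.id for s in fx.query],
    background_hits, [s.id for s in fx.background],
    tf_names={m.id: m.name for m in fx.models},
)

out = "site_map_example.svg"
render_site_map(query_hits, fx.query, out, SiteMapSpec(), enrichment=rows)
print(f"wrote {out}: {len(query_hits)} site(s) across {len(fx.query)} query sequences")

# Display filters (deficit_filter, p_filter, tfs_shown) only hide glyphs in
# the figure; the site and enrichment tables are never altered by plotting.
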