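# Methods

## Scoring model

A position frequency matrix (PFM) of length L holds non-negative counts
`counts[i, B]` for B ∈ {A, C, G, T}. Counts become frequencies with an
additive pseudocount p applied equally to each base:

    f(i, B) = (counts[i, B] + p) / (Σ_B counts[i, B] + 4p)

The default total p = 0.8 (0.2 per base in effect) keeps every frequency
strictly positive — required because the information vector takes
logarithms — while perturbing well-sampled columns by under 2% for typical
matrix depths. A uniform column stays uniform under this smoothing. The
pseudocount is configurable per call.

Per-position conservation is the information vector

    I(i) = Σ_B f(i, B) · ln(4 · f(i, B))

with natural logarithms; I(i) ∈ [0, ln 4], zero iff position i is uniform.
The log base only rescales the weights and cancels in the normalised score
below, so it is an internal convention, not a tunable.

A window b₁…b_L scores

    score = (Current − Min) / (Max − Min)
    Current = Σᵢ I(i) · f(i, bᵢ)
    Min = Σᵢ I(i) · min_B f(i, B),   Max = Σᵢ I(i) · max_B f(i, B)

which lies in [0, 1]; the consensus (per-position argmax base) scores
exactly 1 and the anti-consensus exactly 0. A fully uniform matrix has
Max = Min and is rejected at model-building time rather than scanned.

## Core selection and the two-stage scan

The *core* is the five consecutive positions maximising Σ I(i); ties break
to the leftmost (5′-most) window so the choice is deterministic and
order-independent. Matrices shorter than five positions are rejected at
parse time with a warning (padding would invent signal). Any core
definition present in a TRANSFAC file is ignored; the core is always
recomputed from the information vector so JASPAR and TRANSFAC libraries
behave identically.

Scanning slides the 5-base core over the sequence (both strands by
default). Where the core similarity reaches the threshold `1 − deficit`,
the single full-length window whose core aligns with that 5-mer — starting
at p − offset for a core match at p — is scored; windows that would
overhang the sequence are discarded. A site is reported when core AND
matrix scores both reach the threshold (default deficit 0.15, i.e. accept
≥ 0.85; the identical cut-off applies to both scores). Because the core
score of a window is a necessary condition checked by the prefilter with
the same threshold, the two-stage scan is exactly equivalent to scoring
every window; the test suite verifies this equivalence against an
exhaustive pure-Python oracle on random fixtures. Threshold comparisons
carry a 1e-12 slack so that windows mathematically at the boundary
(notably the consensus at deficit 0) are not lost to floating-point
rounding.

Minus-strand scanning reverse-complements the sequence (equivalent to
reverse-complementing the matrix) and maps hits back to forward-strand
coordinates. A palindromic site passing on both strands is reported once
per strand and never merged: downstream enrichment counts *sequences*, so
the duplication cannot inflate statistics. Windows containing N are
rejected by default (`n_policy="reject_window"`); the alternative
`zero_weight` mode lets N contribute each position's minimum frequency,
which is the most pessimistic score consistent with an unknown base.

## Promoters and the TSS table

From an Ensembl-style GTF, each `transcript` feature yields one record
(gene id, gene symbol, transcript id, chromosome, 0-based TSS, strand);
the table round-trips through a 6-column TSV. Identifier lists match
case-insensitively against symbol, then gene id, then transcript id; a
gene-level match returns all of that gene's transcripts, and unmatched ids
are returned, never dropped.

The promoter window default is 1500 bases upstream to 500 downstream of
the TSS. The TSS base is counted inside the downstream window — a choice
the upstream/downstream convention leaves open — so the default yields
exactly 2000 bases: on '+' the interval is [tss − 1500, tss + 500), on '−'
the mirror [tss − 499, tss + 1501), and extraction reverse-complements so
the base at promoter offset 1500 is always the TSS base. Windows are
clipped at position 0 and at contig ends (with a warning) rather than
erroring; identical (chrom, start, end, strand) promoters are
deduplicated. All coordinates are 0-based half-open internally; BED is
native, GFF/GTF are converted on read.

## Enrichment statistics

For each TF the counts (n_S of N_S query, n_B of N_B background sequences
with ≥ 1 site) form a 2×2 bound/unbound table. The primary test is
Fisher's exact test, two-sided by the probability-mass rule (sum of
hypergeometric probabilities of tables at most as probable as observed);
two-sided is the conservative choice when the direction is not fixed a
priori, and the signed significance score carries the direction anyway.
The Mann-Whitney U test on sites-per-sequence (zeros included) is optional:
exact, tie-aware enumeration of all C(n₁+n₂, n₁) group assignments when the
combined sample size is ≤ 20, otherwise the normal approximation with tie
correction. The summary statistics use half-count corrections:

    avg_log2_prop_bound = ½·log₂((n_S+½)/(N_S+½)) + ½·log₂((n_B+½)/(N_B+½))
    log2_enrichment     = log₂((n_S+½)/(N_S+½)) − log₂((n_B+½)/(N_B+½))
    significance_score  = −sign(log2_enrichment) · log₁₀(p)

with sign(0) = 0, so a TF with identical proportions gets score 0
regardless of p. Swapping query and background negates `log2_enrichment`
and `significance_score` and leaves the Fisher p unchanged. Raw p-values
are reported by default; Benjamini–Hochberg adjustment is available behind
a flag (`with_fdr`) since typical use ranks a few hundred TFs. The query
and background must be scanned with the same deficit; `run_enrichment`
rejects mismatched criteria when both are declared.

## Synthetic data

`matchscan.synthetic` generates everything the pipeline consumes: random
PFMs with one dominant base per position (sharply conserved columns, as in
curated libraries), toy genomes with matching GTFs, and planted-motif
benchmarks. The default benchmark models a promoter-set experiment: 50
query and 50 background sequences of 600 bases at 45% GC (mammalian
promoter-like composition), one planted TF whose exact consensus is
inserted at a random position and strand in 80% of query and 10% of
background sequences, plus four decoy TFs that are never planted. Planted
positions/strands are recorded in a truth table, and because planted
instances are exact consensi (score 1.0) a deficit-0 scan must recover
every one. All generation flows from one `numpy` Generator seeded by the
spec, so identical specs give byte-identical FASTA output.

What the generator does *not* emulate: real promoter base composition
(CpG islands, repeats), degenerate motif instances below consensus,
overlapping or clustered sites, and shared information between TF models
(paralogous matrix families). A green planted-recovery test therefore
establishes that the pipeline detects a strong differential signal against
i.i.d. background — not calibrated performance on genomic sequence, which
depends on the background set the user supplies.

## Numerical and design notes

- Scan vectorisation uses a (L × 5) weight table I(i)·f(i, B) with an N
  column of −∞ (reject mode) or the per-position minimum weight
  (zero-weight mode); sliding windows are numpy views, so scanning is
  O(sequence length) per matrix with small constants.
- Exact Fisher computation is delegated to `scipy.stats.fisher_exact`; the
  test suite holds it to 1e-10 relative agreement with an exact-integer
  hypergeometric enumeration over all margins ≤ 30.
- The exact Mann-Whitney branch compares |U − n₁n₂/2| with a 1e-9 slack to
  absorb midrank floating error; the permutation distribution of U is
  symmetric about n₁n₂/2 (reversing the pooled order is an involution that
  preserves ties), so this equals the usual two-tailed rule.
- Site tables and enrichment tables are plain TSV via pandas; BED6 export
  encodes round(1000·matrix_score) in the score column.
- The site-map figure is a static SVG/PNG (one track per sequence,
  strand-marked glyphs, legend limited to the TFs shown — top ten by
  significance by default). Display filters only hide glyphs and never
  modify tables; a test hashes the tables before and after rendering.

## Known limitations

- Match scores are similarity ratios, not calibrated p-values; comparing
  scores across matrices of very different information content is
  qualitative.
- Enrichment treats sequences as exchangeable; GC- or length-matched
  background construction is the user's responsibility (backgrounds are
  explicit sequence sets by design).
- The GTF reader targets Ensembl-style attributes (`gene_id`,
  `transcript_id`, optional `gene_name`); other dialects may need
  pre-processing.
- Dinucleotide, HMM or machine-learned binding models are out of scope.
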