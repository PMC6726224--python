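"""From a gene list to promoter sequences.

Builds a TSS annotation table from a (synthetic) Ensembl-style GTF, resolves
gene symbols / IDs, takes the default promoter window (1500 bases upstream to
500 downstream of the TSS, TSS base included) and extracts strand-aware
sequences from the genome.
"""

import numpy as np

from matchscan import build_glm, extract_sequences, promoters, resolve_ids
from matchscan.synthetic import random_genome_gtf

rng = np.random.default_rng(1)
genome, gtf_text = random_genome_gtf(rng, n_chroms=2, n_genes=6)

glm = build_glm(gtf_text)
print(f"TSS table: {len(glm)} transcript(s), e.g. {glm[0]}")

matched, unmatched = resolve_ids(["GENE1", "GENE2", "NOT_A_GENE"], glm)
print(f"resolved {len(matched)} transcript(s); unmatched: {unmatched}")

intervals = promoters(matched)  # default window (-1500, +500)
seqs = extract_sequences(genome, intervals)
for iv, s in zip(intervals, seqs):
    print(f"  {iv.name}: {iv.chrom}:{iv.start}-{iv.end} ({iv.strand}) "
          f"-> {len(s.seq)} bases, starts {s.seq[:12]}...")

# Each promoter is 2000 bases (unless clipped at a contig edge); on the minus
# strand the sequence is reverse-complemented so position 1500 is the TSS base.
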