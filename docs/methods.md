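# Methods

## Pipeline model and assumptions

The pipeline treats a metatranscriptome read set as a mixture of four read
classes — rRNA/tRNA carry-over, phiX spike-in, transcripts of annotated
protein-coding genes, and intergenic transcription — and assigns each read
by the best local alignment of its unique sequence. Core assumptions:

- **Best-hit rule.** Taxonomy and function derive from the single top-scoring
  alignment (ties broken by bit score, then identity, then subject id).
  Equal-best hits in different genera set an `ambiguous` flag but are not
  re-resolved by lowest common ancestor, because the threshold calibration
  measures the confidence of exactly this rule; changing the rule would
  invalidate the thresholds.
- **Strand-agnostic transcripts.** Library construction from double-stranded
  cDNA destroys transcript orientation, so gene/intergenic classification
  ignores strand and both strands are always searched.
- **Dereplication is lossless compression.** Identical sequences are pooled
  (qualities ignored, first-seen representative kept); every downstream
  abundance is re-expanded by cluster multiplicity, so the conservation
  identity `Σ multiplicities = quality-passed reads` must hold exactly at
  every stage.

## Thresholds and parameters

All cutoffs live in one `Thresholds` record:

| parameter | default | meaning |
|---|---|---|
| `q_min` | 10 | minimum mean Phred; boundary inclusive (mean == 10 is kept) |
| `rrna_min_bit` | 54 bits | filter-database removal cutoff, inclusive |
| `t_genus` / `t_family` / `t_func` | 148 / 110 / 74 bits | half-open binning intervals [148,∞), [110,148), [74,110) |
| `blastx_min_bit` | 40 bits | translated-search salvage cutoff |
| `cog_evalue_max` | 1e-6 | COG assignment from protein alignments |
| `capture_fraction` | 0.95 | significant-gene selection |
| `salvage_fraction` | 0.10 | unassigned-read subsample (round-half-even) |
| `orf_overlap_fraction` | 0.50 | gene vs intergenic rule, inclusive |
| `conf_phylo` / `conf_cog` | 0.80 / 0.95 | calibration confidence targets |
| `word_size_pass1` / `word_size_pass2` | 28 / 11 | seeding word sizes of the two alignment passes |

## Built-in aligner

The built-in backend is an exact-word seed-and-extend local aligner: all
`word_size`-mers of the reference are hash-indexed (homopolymer words
skipped as a minimal low-complexity guard); query seeds are grouped by
diagonal into subject windows, and each window is resolved by a full
affine-gap Smith–Waterman with traceback (numba-compiled). The window
margin defaults to the query length, generous enough that any local
alignment passing through a seed lies inside the window — on seeded
instances the heuristic provably returns the exhaustive-DP optimum, which
the test suite checks against an independent dynamic-programming
implementation on hundreds of random instances.

Scoring defaults: match +1, mismatch −2, gap of length L costs
−5 − 2(L−1). Bit scores use the ungapped Karlin–Altschul parameters
published for the +1/−2 ratio, λ = 1.33 and K = 0.621, reused as stated
approximations for these mildly gapped alignments. Under this scheme a
perfect 101-nt read scores ≈195 bits and a ~15%-diverged alignment ≈110
bits, so the 148/110/74 cutoffs partition realistic read alignments; note
that pairing match = +1 with the frequently quoted λ = 0.625, K = 0.41
(which belong to +2/−3 scoring) would cap 101-nt reads at ≈92 bits and make
the genus bin unreachable. All five parameters are configurable and recorded
in result headers. E-values (`K·m·n·e^{−λS}`) are reported for information
only; every decision in the pipeline uses bit scores, except COG assignment
from protein alignments which uses the supplied e-values.

The translated search translates all six frames, splits at stop codons, and
aligns every stop-free segment against the protein database under BLOSUM62
(gaps −11/−1, λ = 0.267, K = 0.041). It is exhaustive by design and intended
for the small salvage databases of the test environment, not genome-scale
search.

External aligners are supported at two seams: pass-1 rRNA filtering accepts
any callable mapping clusters to matched filter records (wrapping e.g. a
dedicated rRNA screener), and the genome-alignment stage accepts a
precomputed 12-column tabular alignment file in place of the built-in
backend.

## Threshold calibration

`calibrate` draws reads uniformly over (gene, offset, strand) from the
reference's coding sequence, re-aligns them, and computes per-rank
confidence `n_correct / n_assigned` on the exact grid of observed best-hit
bit scores (no fixed step, so the extracted minimal threshold is exact).
Correctness compares taxon *names* from the lineage table, not genome
identifiers, since draft genomes can share names across ids. The default
self-hit policy leaves the source gene in the database — matching a
simulation drawn from the aligned reference — with a `mask-source-gene`
mode as a harder variant. A reference with a single genome makes every
phylogenetic rank trivially correct; such curves are flagged `degenerate`
rather than suppressed. If the target confidence is never reached the
extracted threshold is the sentinel `"unreachable"`, not an exception.

## Synthetic mock community

The generator emulates the data regime this pipeline targets: few dominant
genera, heavily skewed expression, large rRNA carry-over. Sizing defaults
(chosen once as this package's study conditions): 3 genera × 2 genomes ×
12 genes of 400–500 bp (~32 kb of coding sequence), rRNA read fraction
0.83, phiX 0.01, intergenic 0.02, substitution error rate 0.005, read
length 101 nt, 100,000 reads — giving ~50× mean mRNA depth per gene.
Genomes descend from one community root sequence mutated at the
inter-genus rate (0.15) per genus ancestor and the intra-genus rate (0.02)
per genome; this parameterisation (rather than independent genus
ancestors, which would pin inter-genus divergence at ~0.75) makes genera
controllably confusable, which is what the threshold calibration needs.
Per-gene expression is log-normal (σ = 1.5), reproducing the regime where
the top-ranked genes capture 95% of reads. Each genome carries one copy of
a community rRNA operon template (4 kb, 1% diverged per genome — the
operon is far more conserved than coding sequence); the template also
seeds the filter database together with synthetic tRNAs, adapters and a
fixed-seed phiX-like decoy (labelled synthetic; it is not the real phiX-174
genome). Qualities follow a two-band model (Q38 high / Q12 low, 5% low).

What the generator does **not** model — and hence what passing tests do not
demonstrate about real data: codon structure (genes are uniform random
sequence with planted spans; translated-search tests plant real ORFs where
needed), indels and instrument-specific error profiles, amplification bias,
rRNA secondary structure, and the database-incompleteness that dominates
real unassigned fractions. On real data the genus-binned fraction and the
calibrated thresholds depend on the reference database, not only on the
method.

## Numerical and design choices

- Internal coordinates are 0-based half-open; all tabular alignment I/O is
  the 1-based inclusive 12-column dialect with `sstart > send` encoding the
  minus strand. Bit scores are written at 2 decimals, identities at 3.
- Threshold boundaries are inclusive at the named value everywhere ("minimum
  X of N" admits N): quality 10, filter 54, bins 74/110/148, overlap 0.50.
- Ties: best hit by (bit desc, identity desc, subject id, strand, position);
  max-overlap gene ties by lower gene id; significance ranking ties by gene id.
- Gene coverage uses each distinct cluster once (multiplicity is abundance,
  not extra sequence) and clips alignment spans to the gene span.
- The 10% salvage subsample size uses banker's rounding; the subsample is a
  seeded uniform draw without replacement.
- Normalization (`count / total × mean(totals)`) restores each dataset's
  total to the mean exactly in exact arithmetic; tests assert it to float
  precision (relative 1e-9).
- Pearson p-values use the exact t-transform with n−2 degrees of freedom.
- KO assignment is an input table (gene → KO); the web-service annotation
  step used in practice is neither offline-reproducible nor versioned, so it
  is deliberately out of scope. iPath widths use raw multiplicity-weighted
  read counts by default (a flag switches to normalized values).
- The run manifest checks all stage-partition identities and the pipeline
  aborts if any is violated; stages exchange files in the documented text
  formats so any stage can be replaced by an external tool.

## Known limitations

- The built-in aligner is intended as the reference/test backend; for
  genome-scale references a production aligner should feed the tabular
  import path.
- Paired-end mode draws both mates from one insert inside a single feature,
  so intergenic reads (spacers shorter than the insert) are skipped there.
- Calibration on error-free self-hit data is trivially confident; the
  holdout re-check with substitution noise (5%) is the meaningful exercise.
- COG categories of the synthetic community are planted via the gene product
  field; real references must supply a COG → category map.
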