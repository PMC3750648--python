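# mtxpipe

A metatranscriptome RNA-seq read-assignment pipeline for prokaryote-dominated
communities, written for microbiome researchers who need to turn raw Illumina
cDNA reads into taxonomic and functional activity profiles. It covers the
classic short-read workflow: mean-quality filtering, identical-read
dereplication, two-pass in-silico removal of rRNA/tRNA/phiX/adapter
carry-over, two-pass alignment to a reference genome set, bit-score-threshold
binning of reads into genus / family / function-only / unassigned classes,
gene-level expression with significance selection and coverage profiling, and
COG/KO functional profiles with iPath export. A synthetic mock-community
generator produces fully truth-labeled inputs, so every stage is testable
without downloading any reference data.

## The method

Reads are pooled into unique sequences (clusters) with a multiplicity, then
screened in two passes against a filter database of rRNA loci, tRNAs, the
phiX spike-in and sequencing adapters; a cluster is removed when its best
local alignment reaches **54 bits**. Surviving "mRNA" clusters are aligned to
the genome database in two passes — a fast pass with word size 28, then a
sensitive word-size-11 pass for clusters left below 74 bits — and binned by
the bit score *B* of their best hit:

    B = (λ·S − ln K) / ln 2

with raw Smith–Waterman score *S* and Karlin–Altschul parameters (λ, K) of
the scoring scheme (defaults: match +1, mismatch −2, gaps −5/−2, λ = 1.33,
K = 0.621). The half-open bins are

| best-hit bits | assignment |
|---|---|
| ≥ 148 | genus + family + function |
| [110, 148) | family + function |
| [74, 110) | function only |
| < 74 / no hit | unassigned |

These cutoffs are not arbitrary: the `calibrate` module re-derives them by
simulating reads of known origin from the reference, measuring per-rank
confidence (correct / assigned under the best-hit rule) as a function of the
threshold, and extracting the minimal threshold reaching 80% confidence for
phylogenetic ranks and 95% for COG assignment.

Genome-assigned reads with ≥ 50% of their alignment length inside an
annotated ORF are gene-assigned (max-overlap rule); "significant" genes are
the shortest count-ranked prefix capturing 95% of gene-assigned reads.
Cross-dataset comparisons use mean-total normalization
(`count / dataset_total × mean(totals)`), Pearson correlation on normalized
counts, and multiplicity-weighted COG category profiles (total scope at
≥ 74 bits, genus scope at ≥ 148 bits), with KO-aggregated log2 read counts
exported as iPath line widths.

## Worked example

Simulate a small mock community (3 genera × 2 genomes, 83% rRNA carry-over,
101-nt reads) and run the pipeline on it:

```bash
python - <<'EOF'
import json
from mtxpipe.simdata import CommunitySpec, spec_to_json
json.dump(spec_to_json(CommunitySpec(n_reads=3000, seed=5)), open("spec.json", "w"))
EOF
mtxpipe simulate --spec spec.json --outdir sim > paths.json
# build run.json from the printed paths (reads, references, filter db), then:
mtxpipe run --config run.json
```

The run prints `conservation identities hold: True` and writes
`run/report.txt`, which for this seed begins:

```
## Phylogenetic profile (genus level, read fractions)
  Genus00                    0.2545
  Genus01                    0.4020
  Genus02                    0.3434

## Read bins (multiplicity-weighted)
  genus                   495
  family                    0
  function_only             0
  unassigned                0
  gene-assigned           417
  intergenic               78
```

Reading: of the 3,000 simulated reads, the rRNA/phiX filter removed the
~84% carry-over; all 495 surviving mRNA reads aligned at ≥ 148 bits (the
simulated genomes are the aligned database, so every read is genus-binnable),
417 of them inside ORFs and 78 in intergenic spacers; the genus fractions
match the community's skewed expression draw. `mtxpipe calibrate --refs sim
--n 150 --len 100 --seed 17 --out thresholds.json` then re-derives per-rank
minimum thresholds from labeled simulated reads (on error-free self-hit data
every rank's threshold collapses to the minimum observed bit score,
192.57 bits here).

## Layout

- `mtxpipe.iokit` — data model, FASTQ/FASTA/tabular-alignment I/O, reference bundle
- `mtxpipe.preprocess` — quality filter, dereplication
- `mtxpipe.rrna_filter` — two-pass filter with pluggable pass-1 backend
- `mtxpipe.aligner` — seed-and-extend local aligner, bit scores, translated search
- `mtxpipe.assign` — binning, phylogenetic profiles, pair congruence, salvage
- `mtxpipe.genes` — gene/intergenic classification, significance, coverage
- `mtxpipe.profiles` — COG/KO profiles, normalization, iPath, comparisons
- `mtxpipe.calibrate` — threshold calibration by read simulation
- `mtxpipe.simdata` — mock community and read simulator
- `mtxpipe.pipeline` / `mtxpipe.cli` — orchestration, manifest, reports

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
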