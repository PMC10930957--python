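# orispan

Tools for quantifying genes that span the linearization origin of a
circular genome — such as the lncRNAs MDL1 (heavy strand, 15,954–576) and
MDL1AS (light strand, 16,024–407) transcribed across the D-loop of the
16,569 bp human mitochondrial genome — and for evaluating them as survival
biomarkers.

When a circular genome is cut at its conventional origin to make a linear
reference, any read that straddles the cut point becomes unmappable and
the genes crossing the origin are silently under-quantified. `orispan`
provides the full analysis path around that problem:

- **`orispan.circular`** — 1-based circular coordinate algebra: wrapping
  intervals (`start > end`), reference rotation with an invertible
  `RotationMap`, annotation lifting, and junction-padded linear references
  on which every circular read placement is visible exactly once.
- **`orispan.io`** — FASTA and GTF reading/writing. Wrap-around genes are
  serialized as two exons of one transcript (the only GTF-legal encoding)
  and reassembled on read.
- **`orispan.readsim`** — strand-aware short-read simulation from circular
  transcript models, with substitution errors, FASTQ output, and a sidecar
  truth table.
- **`orispan.quant`** — a desk-scale seed-and-extend mapper (exact k-mer
  seeds, Hamming extension, canonical circular positions),
  featureCounts-style overlap counting with explicit ambiguity handling,
  RPKM normalization, and a junction-loss report comparing the naive and
  rotated references.
- **`orispan.cohort`** — synthetic survival cohorts: group-wise
  moment-matched lognormal expression, exponential survival whose hazard
  depends on expression relative to a true cutoff, administrative and
  dropout censoring. `default_larc_cohort()` carries the published
  69-patient cohort structure as simulation targets.
- **`orispan.groupstats`** — one-way ANOVA, Welch's t, Pearson chi-square,
  Sidak and Benjamini–Hochberg adjustments.
- **`orispan.survival`** — empirical ROC with exact trapezoid /
  Mann–Whitney AUC and DeLong CI, Youden-index cutoff with Wilson CIs,
  Kaplan–Meier, log-rank (Mantel–Cox), univariate Cox PH (Newton–Raphson,
  Efron ties), 5-year survivor labelling, and an end-to-end
  `biomarker_report`.

## Command line

```sh
# rotate a circular reference so origin-spanning genes become contiguous
orispan rotate --fasta ref.fa --gtf genes.gtf --origin 8000 --pad 149 \
    --out-prefix rotated

# simulate a stranded library with truth table
orispan simulate-reads --fasta ref.fa --gtf genes.gtf --n 10000 \
    --read-length 100 --error 0.001 --strandedness reverse --seed 7 \
    --out reads.fq

# map and count on the rotated reference
orispan quantify --fasta rotated.fa --gtf rotated.gtf --fastq reads.fq \
    --strandedness reverse --max-mismatch 2 --out counts.tsv

# synthetic survival cohort and biomarker evaluation
orispan simulate-cohort --seed 1 --out cohort.tsv
orispan biomarker --cohort cohort.tsv --gene MDL1AS --out report.json

# group comparisons with multiplicity adjustment
orispan compare --expr expr.tsv --meta meta.tsv --adjust sidak
```

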