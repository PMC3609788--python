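# Methods

## The analysis model

The pipeline identifies direct targets of a transfected miRNA by combining
physical evidence (co-precipitation with Argonaute-2, the catalytic core of
RISC) with functional evidence (mRNA repression after transfection) and
sequence evidence (a seed-match heptamer in the 3′UTR).

**Quantification.** Each of the four sequencing libraries (total-RNA and
Ago2-IP, in transfected and non-transfected cells) is reduced to gene-level
RPKM: `rpkm = 1e9 * C / (N * L)` with count `C`, total mapped reads `N`, and
gene length `L` in bp. Within a condition the *abundant-Ago2 fraction* is
RPKM(IP)/RPKM(total); gene length and library depth cancel, so it is a
relative RISC-occupancy measure. The *fold-enrichment score* is the ratio of
abundant-Ago2 fractions, transfected over non-transfected. Under a
no-recruitment null with IP sampling proportional to expression, the score
is centred at 1.

**Evaluability.** Genes with total-RNA RPKM below a floor (default 0.5) in a
required condition are excluded rather than smoothed: ratios of
near-zero RPKM are numerically unstable, and pseudocounts would change the
score's definition. Genes whose non-transfected fraction is exactly zero are
likewise non-evaluable (the score would be infinite). Ranking is descending
by score with gene-id tie-break, so "top X%" is a total order.

**GSEA.** The enrichment statistic is the classic weighted
Kolmogorov–Smirnov walk: along the expression ranking (log2
transfected/control, descending; duplicate measurements per gene averaged
first), hits add `|metric|^p / Σ|metric|^p` and misses subtract `1/(N−Nh)`;
ES is the signed maximum deviation, so ES ∈ [−1, 1]. The weight exponent
defaults to `p = 1`. Because the design has a single (duplicate-averaged)
array per condition, a phenotype-permutation null is impossible; the null is
instead generated by resampling random gene sets of the same size from the
ranked universe. NES divides ES by the mean |ES| of same-sign null draws;
the permutation p-value is the fraction of same-sign nulls at least as
extreme; the FDR q compares the observed NES against the pooled
sign-normalized null (with a single observed set, the denominator of the
standard pooled-null ratio is 1). If no same-sign null draw exists, NES is
flagged as undefined. p-values under a random ranking are uniform (verified
by KS test in the suite).

**Cut-off scan.** For each rate r on a grid (default 1–100% in 1% steps) the
top r% of the fold-enrichment ranking — optionally restricted to the
seed-motif universe first — is tested as a gene set; the optimum is the rate
with the most negative NES, ties broken toward the smaller rate. The
per-rate permutation seed is derived from (seed, set size), so adjacent
rates whose top sets coincide get identical NES (a plateau, not noise).
Rates with empty or universe-spanning sets are skipped. Note the optimum
tracks the planted-target share *of the scanned universe*: scanning the full
gene universe with 5% planted targets localizes near 5%, while scanning the
motif-filtered universe (where targets are concentrated) localizes near the
targets' share of that universe.

**Candidates and pathways.** Final candidates are top-set genes with linear
transfected/control ratio strictly below 1/fold (default fold 2; ">2-fold
decrease" is read as ratio < 0.5, strict, matching the printed inequality
conventions used throughout: growth ratio < 0.8, < 0.5-fold expression,
frequency > 50%). Over-representation is the one-sided hypergeometric tail
P(X ≥ overlap) per gene set with BH correction across sets. The ORA universe
is the set of genes evaluable in both the enrichment and expression stages,
avoiding composition bias from non-evaluable genes; using the whole genome
instead is a config choice. Clinical-style summaries are Pearson
product-moment correlation (t-distribution p; undefined and flagged at zero
variance) and the per-gene fraction of evaluable tumor/non-tumor pairs with
T/N strictly above fold (missing pairs shrink the denominator).

**Screening triage.** A miRNA is a functional hit if its growth ratio is
strictly < 0.8 in at least `min_hit_lines` (default 4) of the cell lines;
"more than 3 of 6" is read as ≥ 4, configurable. A miRNA is commonly
downregulated if it is strictly > 2-fold below the reference summary in ALL
cell lines, where the reference summary is the minimum over the normal
reference samples — downregulation must hold against both references; the
mean is the obvious alternative and is a one-line change. A value missing in
a line counts as not-downregulated there, so an incompletely quantified
miRNA never qualifies. Candidates are the intersection of the two arms.
Panel frequencies use < 0.5-fold (cell lines vs reference; tumor vs its
paired non-tumor) with a strict > 0.5 frequency cut.

## The seed motif

The scanner searches the printed heptamer `ACGACGA` on the sense strand
only, counting overlapping occurrences; `N` never matches. Presence/absence
is what downstream consumes. This heptamer is the reverse, not the reverse
complement, of the miR-15/107-family seed AGCAGC(A); the canonical
Watson–Crick site would be `TGCTGCT`. The scanner takes the motif as a
parameter, so either convention can be run; the default follows the printed
sequence.

## The synthetic generator

`simulate_transcriptome` draws per-gene baseline abundance from a log-normal
(default ln-mean 0, ln-sd 1), gene lengths uniform on 500–5000 bp, and
counts for each library from a negative binomial (shared dispersion,
default 0.1; var = μ + 0.1μ²) around means proportional to
expression × length, scaled to the library size (default 2×10⁶ reads; chosen
for desk-scale runtime, not to mimic a specific sequencing depth). Ago2-IP
means equal expression × a constant IP affinity, so non-target scores are
centred at 1 by construction; true targets (default 5% of genes) carry a 4×
multiplier in the transfected IP fraction and a 1/2.5 multiplier in the
transfected total/expression data. Array expression adds log2-normal noise
(sd 0.25, a typical array replicate sd). UTRs are uniform random DNA
(200–2000 bp) with ≥ 2 motif copies planted in non-overlapping windows of
each true target's UTR; background motif hits occur by chance at the
analytic rate 1−(1−4⁻⁷)^(L−6). One library per fraction/condition, no
replicates, matching the single-sample design the pipeline addresses.

`simulate_screen` plants `round(470 × ts_mirna_fraction)` (default 10)
TS-miRNAs whose growth ratios are centred at 0.6 (Gaussian noise sd 0.1,
truncated at 0) in every line and whose expression is 0.2× the reference in
cell lines and 0.3× the paired non-tumor in tumors; all other miRNAs are
centred at ratio 1. The expression panel has 2 normal references, the 6
lines, and 18 tumor/non-tumor pairs.

The generator also emits a GMT collection whose `CELL_CYCLE` set contains
half the true targets diluted 1:1 with random non-targets, plus 19
size-matched random sets, so pathway over-representation of recovered
candidates is testable with known ground truth.

**What the generator does not emulate:** read-level data (no FASTQ or
alignment), positional/fragment bias, isoforms, gene–gene count correlation,
batch effects, or real pathway structure. Passing tests therefore show the
*inference machinery* is correct and calibrated under a realistic noise
model — not that the biological conclusions transfer to any particular real
dataset.

## Numerical choices and degenerate inputs

- A ratio of four independent NB counts is Jensen-biased upward
  (≈ (1+CV²)² ≈ 1.2 at dispersion 0.1), so null centering of the
  fold-enrichment score is asserted on the log scale / median, where the
  per-library biases cancel; the arithmetic mean is not 1 and no correction
  is applied to the score itself, which keeps the printed definition exact.
- GSEA with an all-zero metric falls back to equal hit weights (the
  weighted increment is otherwise 0/0).
- Empty gene sets, sets equal to the whole universe, zero-length genes,
  zero library totals, unpaired tumor samples, and non-positive expression
  all raise with the offending items named.
- All randomness flows through `numpy.random.default_rng` seeded from the
  config; the transcriptome, screen, and analysis stages use separate
  spawned streams so each is independently reproducible. Writers use fixed
  float formatting and sorted JSON keys, making CLI reruns byte-identical.

## Problem sizes in the suite

Unit tests run at 300–2,000 genes; recovery and calibration tests at the
default 4,000-gene / 470-miRNA conditions over 10 seeds with 100–200
permutations per GSEA test, and 50 null replicates at 1,000 genes with a
fixed 5% cut-off (the null calibration probes the ORA stage, for which the
NES scan is irrelevant; fixed-rate mode is a first-class pipeline option).
These sizes make the whole suite run in well under a minute while leaving
the planted effects comfortably detectable.

## Known limitations

- The fold-enrichment score has no variance stabilization; very
  low-expression genes are handled only by the RPKM floor.
- The FDR q is the single-set pooled-null variant; batch FDR across many
  gene sets is out of scope.
- The cut-off scan's NES profile at small set sizes is permutation-noisy;
  with few permutations the optimum can wander among adjacent rates (the
  suite's ±5-percentage-point tolerance reflects this).
- Leading-edge extraction and thermodynamic/conservation-based target
  prediction are not implemented.
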