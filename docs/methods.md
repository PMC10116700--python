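# Methods

## Design

All analyses operate on normalized abundance matrices (FPKM for genes,
TPM for miRNAs) over a fixed sample design: two genotypes × five seed
developmental stages (S1–S5) plus flag leaf × biological replicates.
Flag leaf is the vegetative control: differential expression is always
a within-genotype contrast of a seed stage against that genotype's own
leaf, which removes constitutive genotypic differences before the two
genotypes' stage-wise results are compared.  Transposable-element
flagged genes are dropped when the annotation is loaded.

## Expression filters

"Expressed" is evaluated on the replicate mean per (genotype, tissue):
a feature is expressed when the mean reaches the threshold (FPKM 1,
TPM 50) in at least one tissue of interest, comparison inclusive.  The
data do not say whether a single replicate or the mean should clear the
cut; the mean is used because per-stage abundance is what the
downstream rules consume.  Seed specificity additionally requires the
leaf mean to stay **strictly** below the threshold — the boundary
conventions (≥ for expressed, < for the control side) are asymmetric on
purpose and are covered by explicit boundary tests.

## Differential expression

Effect size is `log2((mean_stage + c) / (mean_leaf + c))` with
pseudocount `c = 1`, which bounds fold changes when the control mean is
zero and matches the log2(FPKM+1) transform used elsewhere.  Evidence
is a Welch two-sample t-test on log2(abundance + 1) replicate values;
p-values are Benjamini–Hochberg adjusted across features within each
(genotype, stage) contrast.  The original count-model tests (isoform
deconvolution for genes, negative-binomial for small RNAs) need
read-level data that is outside this package's scope; the pipeline
contract is the thresholding downstream, and the Welch stand-in is
validated by a null calibration test (type-I error within binomial
error of 0.05 at 3 vs 3 replicates).  When both groups have zero
variance the t statistic is undefined; we return p = 1 if the means are
also equal and p = 0 otherwise, so noise-free fixtures behave sensibly.

A feature is a DEG/DEM when q ≤ 0.05 AND |log2fc| ≥ 1 (genes) / 2
(miRNAs) AND it is expressed in the stage or the control.  All
comparisons are inclusive.  The expression condition is applied as a
flag at call time (filter-after testing); BH adjustment therefore runs
over all features.  Stage-specific calls require full significance in
the focal stage but only the fold-change condition (log2fc below the
cut) in the other four stages; common-to-all calls require significance
in the same direction in all five stages.

## Stage alignment

Percent similarity between two DEG sets is Jaccard × 100.  The formula
behind the published percent-similarity figures is not stated; Jaccard
is the default because it is symmetric and bounded, and an
`|A∩B|/|B|` variant is available behind `similarity_mode: of_b`.
Similarity is computed per direction and combined over signed
(feature, direction) elements so a gene up in one stage never matches
itself down in another.  Two empty sets score 0, not 100, to avoid
pairing silent stages.  Each stage of genotype B is assigned the
genotype-A stage of maximal combined similarity (ties break toward the
earlier stage); when the per-stage argmaxes form a consistent
non-negative offset the comparable-stage chain is reported.  No global
alignment (dynamic programming, time warping) is attempted — the claim
being reproduced is per-stage.

## TF families and hormones

Family counts tally member genes that are significant-up with
log2fc ≥ 2 per genotype and stage.  A family is significant at ≥ 5
members in some stage; early-preference is
`min(count(S1), count(S2)) − max(count(S3..S5)) ≥ 3` (late mirrored) —
the strictest reading of "at least three more members in early than
late stages", and the one consistent with the published MADS worked
example (margin 22 − 18 = 4).  A family is genotype-stage preferential
when exactly one genotype carries a non-none label.  Opposite patterns
require a stage that is the unique argmax in one genotype and the
unique argmin in the other; ties disqualify.

Hormone-pathway genes are clustered per pathway by k-means (Euclidean,
k-means++, 100 restarts, fixed seed) on per-profile z-scored
log2(FPKM+1) tissue vectors.  Both genotypes' profiles are clustered
jointly — "same gene, different cluster" needs a shared cluster space —
and a gene is divergent when its two profiles separate.  The catalog
cluster counts (auxin 13, ABA 10, GA 10, CK 9, BR 10, ethylene 15,
JA 8, SA 9) are the defaults; they assume catalogs of hundreds of
genes, so the pipeline caps k at one cluster per six profiles for small
catalogs (floor 2) to keep divergence detection from splitting
noise-identical profiles.  Any k is configurable.  Higher-expression
counts use Δlog2(FPKM+1) ≥ 0.5 (inclusive) per stage; smaller
differences count for neither genotype.

## miRNA–target modules

"Negative correlation in expression patterns" is operationalised as
opposed significant differential-expression calls, not a Pearson
correlation of profiles: an all-stage module pairs a miRNA significant
in one direction in all five stages with a predicted target significant
in the opposite direction in all five stages of the same genotype.
Full DEM significance (q, fold and expression) is required in every
stage, the stricter of the two possible readings.  Opposite-regulation
modules require all four conditions across a same-stage or
comparable-stage pair: miRNA up in one genotype's stage and down in the
other's, target regulated the other way round in both.  Target
prediction is an input table; pairs whose target is missing from the
gene DE table are skipped with a logged warning, never an error.
miRNA families are the integer token after `miR` in `osa-miR…`
identifiers; malformed identifiers are an error rather than family 0.
A family is genotype-specific when all of its expressed (TPM ≥ 50)
members are expressed in exactly one genotype.

## QTL overlay

Coordinates are 1-based inclusive (rice annotation convention).  A gene
hits a QTL when its full span lies inside the interval on the same
chromosome — the containment reading of "located within"; an
any-overlap mode is available (`overlay_mode: overlap`).  BED export
converts to 0-based half-open exactly at the boundary.  Candidate lists
from the upstream analyses are summarised per source; a gene in several
sources counts once in the union.

## Synthetic data

The generator emulates the study design (2 genotypes × 6 tissues × 3
replicates) with multiplicative log-normal replicate noise: each
replicate is `mean × 2^N(0, σ²)` with σ = 0.25 by default, matching the
dispersion shape of FPKM data without modelling counts.  Planted
structure, all recorded in a ground-truth JSON:

* **lag** — developmental-program genes of genotype B show at stage s
  the genotype-A mean of stage s−1 (S1 falls back to the leaf
  baseline), so the DEG-similarity matrix peaks at the planted offset;
  housekeeping genes are flat across tissues so similarity is driven by
  the differential program;
* stage-specific genes (8× fold against a leaf-level baseline, split
  evenly over stages and directions), common-to-all-stages genes,
  seed-specific genes (stage mean 5, leaf 0.2);
* TF families with prescribed per-stage upregulated-member counts
  (scaled-down analogues of the early-preferential, late-preferential,
  opposite-pattern, one-genotype-only and below-cut patterns);
* hormone genes per pathway with a divergent fraction (ramp-up in one
  genotype, ramp-down in the other) against two non-divergent
  archetypes chosen to be well separated in z-profile space;
* anti-correlated miRNA–target modules (miRNA 20× against leaf, target
  opposed), a third each specific to either genotype or shared, plus
  opposite-regulation modules over same- and comparable-stage pairs,
  near-miss decoys (up in four of five stages) and decoy target pairs;
* genotype-specific miRNA families, expression levels straddling the
  FPKM 1 / TPM 50 thresholds to exercise boundaries, TE-flagged genes,
  and a gene subset placed fully inside emitted QTL intervals with all
  other genes placed outside them.

One RNG seed drives everything through per-component child streams, so
a fixed seed gives byte-identical files.  What the generator does *not*
emulate: count-level sampling noise (mean–variance coupling), isoform
structure, correlated genes, partial-overlap QTL placement, or
sequence content.  Tests passing on this data therefore demonstrate the
correctness of the rule logic and threshold semantics and the
robustness of set-level conclusions to log-normal replicate noise — not
performance on real sequencing data.

## Problem sizes and determinism

Default simulations use 2000 genes / 300 miRNAs / 3 replicates; module
precision–recall uses 1000 genes / 300 miRNAs with 30 planted modules;
chain-recovery statistics use 20 independent seeds; the null
calibration uses 5000 features.  These sizes give stable set-level
statistics while keeping a full test run within a couple of minutes.
k-means is the only iterative numeric step and is seeded; everything
else is closed-form or exact set arithmetic, so reruns with the same
seed reproduce all outputs byte for byte.

## Known limitations

The Welch stand-in loses power below ~3 replicates and does not share
dispersion information across features; percent similarity is sensitive
to very small DEG sets (a single shared gene can dominate); the CS
chain detector reports only constant offsets, by design; divergence
detection depends on k — too large a k over-calls divergence on noisy
profiles, which is why the pipeline caps it for small catalogs.
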