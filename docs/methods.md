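# Methods

This note documents the statistical models, conventions, and deliberate
design choices behind `serumcmp`, and what the synthetic-data generator
does and does not emulate.

## Study design

All components assume a two-species fibroblast serum-challenge design:
samples are labelled (species, time, replicate) with species in
{human, chimpanzee}, time in {Pre, T0, T12, T24} (pre-starvation,
serum replacement, 12 h, 24 h), and 4 human / 3 chimpanzee biological
replicates by default. Genes are orthologous pairs measured in both
species in one count matrix; accessibility is measured as scored peak
calls (score = −10·log10 p of the call) brought into one coordinate
space before entering the pipeline. Coordinate conventions are 0-based,
half-open (BED) throughout.

## Differential testing (expression and accessibility)

Counts are modelled as negative binomial with variance mu + phi·mu²,
log link, and offset log(lib_size × TMM factor).

**TMM normalization.** Reference column: upper quartile of nonzero
counts-per-library closest to the mean upper quartile. Per column, genes
nonzero in both column and reference are double-trimmed — 30% each side
on M (log ratio), 5% each side on A (mean log abundance) — and the
factor is 2 to the precision-weighted mean of the remaining M values
(delta-method weights). Factors are rescaled to geometric mean 1.
Numeric parity with any external implementation is not a contract;
parity with this stated procedure is, and is tested against a naive
re-implementation.

**Dispersion.** Per-gene dispersion is estimated by Cox–Reid adjusted
profile likelihood on a fixed log-spaced grid (the mean parameters are
profiled out at each grid value and the likelihood is penalized by half
the log-determinant of the Fisher information, removing the bias from
estimating the group means). The estimates are then shrunk 50/50 toward
a lowess mean–dispersion trend and floored at the trend. Two details
matter at the small replicate numbers this design has (6 residual df):

- the lowess trend is fit without robustness iterations, because
  down-weighting the right-skewed high estimates biases the trend low,
  and the likelihood-ratio statistic is convex in 1/phi, so a low trend
  inflates type-I error;
- the floor at the trend (a "maximum" sharing rule) prevents per-gene
  underestimates — overwhelmingly noise at 6 df — from inflating
  individual tests, at the cost of a slightly conservative test for
  genes whose true dispersion is genuinely below the trend.

A simple moment estimator with symmetric 50% shrinkage was evaluated
first and left the null type-I rate at 0.06–0.08 at nominal 0.05; the
procedure above holds it at ~0.04–0.05 (verified by simulation in the
test suite).

**Testing.** The full model fits one mean per group (all group levels
present in the data); the reduced model merges the two contrast levels.
Both are fit by batched IRLS (all genes simultaneously; convergence when
the relative deviance change < 1e-8, 100 iteration cap; non-converged
genes flagged). The LRT is referred to chi-square with df 1; q-values
are Benjamini–Hochberg per contrast and time point; default
significance thresholds are q ≤ 0.10 for expression and q ≤ 0.05 for
accessibility windows. Genes with zero counts in every sample are
dropped before fitting and reported. Dispersions are estimated once from
all samples handed to the test (jointly across groups), matching a
single-model normalization of the full design.

## Enrichment

**Running-sum GSEA.** Genes are ranked by a signed statistic (default:
sign(log2FC) × −log10 p; the exact metric is configurable because no
single convention is canonical). Walking the list, set members add
|stat|^w / Σ|stat|^w (default w = 1), non-members subtract 1/(N − n_set);
ES is the signed maximum deviation, always in [−1, 1]. Significance
uses **gene-label permutation** (membership reassigned uniformly,
preserving set size): with 3–4 replicates per group, sample-label
permutation has too few distinct permutations to be useful, so this is
a deliberate deviation from phenotype permutation. NES divides ES by
the mean |permutation ES| of the same sign; p is the same-sign tail with
add-one correction; collection-level FDR follows the canonical
sign-stratified normalized-score procedure. Ranking ties break by gene
identifier for determinism.

**Hypergeometric categories.** Upper-tail hypergeometric test of a
foreground (e.g. genes up in one species at FDR 0.10) against an
explicit background (all genes active in both species' fibroblasts);
fold = (k/n)/(K/N). The foreground must be a subset of the background.
Category names are compared case-insensitively after whitespace
normalization. "Common" categories intersect all four time points;
"serum-specific" categories subtract the Pre ∪ T0 union from T12 or
T24.

## Window harmonization

"Intersecting DHS sites across all samples" is implemented as a
**boundary partition of the pooled union** (multi-intersect): every
distinct peak start/end across all samples cuts the union into disjoint
segments; covered segments are windows. This is the only reading under
which the window count can exceed any single sample's peak count, as it
does in real data. Book-ended fragments are *not* re-merged — merging
would undo the partition. Windows shorter than 50 bp or longer than
2,000 bp are discarded. Per sample, a window's representative score is
the maximum score of any overlapping peak (= the lowest p-value), 0 if
none; a (species, time) is active if any replicate scores > 0 (no
secondary threshold); a window is shared if active in both species at
any time, species-specific if active in exactly one. These classes
partition the window set by construction, and the partition-sum identity
is asserted in the tests. Differential accessibility reuses the NB-GLM
machinery on window-level read counts (count-based, not score-based).
The direction balance among significant windows is tested with an exact
two-sided binomial test against a configurable reference ratio (which
2×2 construction real analyses used for this is not standardized, so
the construction is exposed rather than fixed).

## Fuzzy trajectory clustering

Per (window, species, time): mean representative score over replicates,
log2(x + 1) (the +1 admits zero activity), then row z-scoring; constant
rows are dropped and counted. The fuzzifier m uses the
Schwämmle–Jensen estimator
m = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406·ln N − 0.1134).
Fuzzy c-means is the standard alternating scheme (Euclidean distance,
membership exponent m), seeded random membership initialization,
convergence when the largest centroid shift < 1e-6; the objective is
non-increasing and memberships are row-stochastic (both property-tested,
and the fixed point is cross-checked against an independent R
implementation). Centroids are reported in canonical order (ascending
final-time value) so labels are reproducible across row permutations.

**Cluster number.** Dmin(c) = minimum pairwise centroid distance at c.
While c does not exceed the number of genuinely distinct trajectory
shapes, centroids stay mutually distant; the first forced split of a
real cluster collapses Dmin. The chosen c is the largest value before
Dmin first falls below 0.1 × Dmin at the low end of the range. (A rule
based on successive drops Dmin(c) − Dmin(c+1) was considered and
rejected: before the collapse the successive drops are themselves small,
so such a rule terminates at the low end regardless of structure.)

**Labels.** A cluster is *opening* if its centroid rises ≥ 0.5 SD units
from T0 (serum replacement) to the final time monotonically (tolerance
0.1 SD per step), *closing* symmetrically, *transient* if the extreme is
interior by the same margin. Windows inherit their highest-membership
cluster's label only at membership ≥ 0.6; below that they are labelled
`other`.

## Gene linking and correlation

Nearest TSS by window-midpoint distance on the same chromosome, strand
ignored for the distance, midpoint ties to the lexicographically smaller
gene id (midpoint-vs-edge and strandedness are conventions declared
here, not inferred from any source). Per-class summaries report windows,
distinct linked genes, and their ratio. "Total DHS signal" per gene is
the sum of representative scores of its linked windows at a time point;
it is correlated with expression by Spearman (average ranks; p by the
large-sample t approximation, exact permutation below n = 10). The
fold-change/activity analysis correlates the between-species expression
log2FC with the per-gene ratio of active windows (pseudocount 1 on both
sides). The PWM scan reports matches at a relative score
(score − min)/(max − min) ≥ 1.0 by default, i.e. only consensus-maximal
words, on both strands via reverse complement; N never matches at 1.0.

## Molecular evolution

Per gene, the isoform with the highest dN represents the gene (ties:
higher dS, then isoform id). A gene is "positive" iff dS > 0 and
dN/dS > 1; dS = 0 genes are excluded from the ratio class and reported
in their own column, since a ratio-defined count cannot include them.
The focal-vs-rest comparison uses a 2×2 Fisher exact test, by default
focal against its complement; the subset-vs-superset construction is
selectable because published analyses do not always state which was
used. dN percentiles are plain empirical percentiles (fraction ≤).

The promoter test uses a ((human, chimp), macaque) alignment per gene
for the promoter (5 kb upstream of the TSS, strand-aware) and nearby
intronic sequence (first introns excluded) as the neutral yardstick.
Columns with gaps or ambiguity codes in any taxon are skipped; a column
is a human-branch substitution iff human ≠ chimp and macaque = chimp
(outgroup parsimony; columns where all three differ are not informative
for the human branch and are skipped). Promoter and intron counts are
compared by a binomial LRT — null: one shared substitution probability;
alternative: separate MLEs — one-sided for promoter > intron: p is half
the chi-square(1) tail in the selected direction and 1 otherwise
(boundary-mixture convention), selected iff p ≤ 0.01 and the promoter
rate exceeds the intron rate. This parsimony-count LRT is a deliberate,
simplified substitution-rate test with a calibrated null (verified by
simulation); it is not a full likelihood phylogenetic model (no
transition/transversion structure, no multiple-hit correction), so its
absolute rates are slight underestimates at high divergence.

## Synthetic data

The generator's defaults are the study conditions used throughout the
tests: 2,000 genes (a deliberate desk-scale stand-in for a ~13k-gene
transcriptome), 4 human + 3 chimpanzee replicates at 4 time points, NB
counts with baseline mean 100 and dispersion 0.1 (per-gene log-normal
jitter, sd 0.25 on the log scale), library sizes log-normal (sd 0.2) so
normalization is exercised, 10% of genes with a ±2 log2FC species
effect, and 5% + 5% serum-response up/down sets that shift ±2 log2FC at
T12/T24 in both species. Windows: 1,000 planted non-overlapping
intervals (100–600 bp) over two 3-Mb chromosomes at the sharing
proportions observed in real fibroblast data (shared 0.475 /
human-only 0.363 / chimp-only 0.162); 30% opening and 30% closing
trajectories (score multipliers 1, 1, 2.5, 4 and 1, 1, 0.4, 0.25 over
the four times); per-sample log-normal score noise (sd 0.15); boundaries
jittered ±20 bp per sample; peaks below score 50 (p > 1e-5) are not
emitted, so closing windows genuinely lose their calls. Alignments: 500
genes × (5 kb promoter + 5 kb intron) on the fixed three-taxon topology
at 0.01 substitutions/site/branch, with a ×5 human-branch promoter rate
for selected genes (10% by default).

What the generator does **not** emulate: read-level noise (mappability,
GC bias, duplicates), genome sequence realism and repeat structure,
cross-assembly coordinate lifting, linked/overlapping genes,
correlated replicate structure, and DHS–expression coupling in the main
bundle (coupling fixtures are generated separately with a Gaussian
copula at a chosen Spearman rho). Passing tests therefore demonstrate
the correctness and calibration of the algorithms under the stated
model, not robustness to these real-data artifacts.

All randomness flows from a single integer seed per config; identical
configs produce byte-identical fixture bundles (checksummed manifest).

## Numerical conventions

- IRLS: eta clipped to ±50, tiny ridge (1e-10) on the normal equations,
  Poisson likelihood limit below phi = 1e-8.
- Running-sum walks clipped to [−1, 1] against float accumulation.
- BH uses the step-up reverse cumulative minimum, capped at 1.
- Degenerate inputs error early with the offending identifier: all-zero
  sample columns (normalization), empty gene-set intersections (GSEA),
  constant vectors (correlation), zero-length alignments.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
default scale above (seconds per stage on one CPU); null-calibration
simulations use 2,000 genes / 500 alignments, sizes at which binomial
Monte-Carlo error is small relative to the tested tolerance bands.
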