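# Methods

This note documents the models, numerical choices and open design
decisions behind `sigreverse`, and what the synthetic-data generators
do and do not emulate.

## The problem and the pipeline

Connectivity-map-style drug repurposing ranks compounds by how strongly
their transcriptomic perturbation profiles *reverse* a disease
expression signature. For a brainstem tumor such as DIPG there is no
matched normal tissue, so the disease signature must be computed
against surrogate controls chosen from a healthy-tissue compendium.
The pipeline therefore has five stages: control selection → signature
construction → reversal scoring → sensitivity-based evaluation → hit
filtering, each usable on its own.

## Autoencoder control selection

The embedding network is a fully-connected autoencoder trained on
log₂(TPM + 1), per-gene standardized with training-set statistics.
Training defaults are 64 encoded features, batch size 128, 100 epochs,
Adam at learning rate 2·10⁻⁴. The published recipe this follows
specifies only "rectifying activation, dropout and normalization
between layers", not the architecture, so the package's default is the
smallest design consistent with that description: encoder widths
[512, 128] → 64 with a mirrored decoder, batch normalization then ReLU
then dropout (rate 0.1) on every hidden layer, linear bottleneck and
output. The implementation is plain numpy with a single seeded
generator for initialization, batch shuffling and dropout masks, so
training is bit-reproducible; batches of size 1 are skipped because
batch statistics are undefined there.

Control selection computes the Pearson correlation (Spearman by flag)
between each normal sample's embedding and each disease sample's
embedding, aggregates across disease samples by the median (robust to
outlier cohort members; the alternative — correlating against a cohort
centroid — is not exposed because the median aggregation subsumes its
robustness rationale), and returns the top k = 100, ties broken by
sample id. Whether the original procedure aggregated per-sample
correlations or used a centroid is not recoverable from its
description; the per-sample + median choice is this package's own.

## Disease signature

**Normalization and filtering.** Library sizes are scaled by TMM
factors (M-trim 0.3, A-trim 0.05, reference = sample with most typical
upper-quartile CPM). Weakly expressed genes — below 1 CPM in fewer
than min(group size) samples — are removed before testing; both
thresholds are configurable.

**Unwanted variation.** Residual structure (cohort/batch effects that
survive a harmonized quantification pipeline) is estimated from
empirical negative-control genes: a first-pass Welch t-test on log-CPM
ranks genes by association with the contrast, and the n least
associated (largest p) serve as controls — the negative-control recipe
of the RUV family. The phrase "empirically differentially expressed
genes" in the source description is ambiguous between most- and
least-DE genes; factor estimation from negative controls requires the
least-DE reading, which is what is implemented. Factors are the top k
left singular vectors of the gene-centered log-CPM block of the
control genes (k defaults to 1 and is configurable; the appropriate k
is dataset-dependent and never stated in the source). CPM rather than
raw log counts is used so that library-size variation cannot
masquerade as the leading factor. The factors can either be regressed
out of the matrix or, as in the pipeline, supplied to the GLM as
covariates (standardized, centered).

**Differential expression.** Each gene gets a negative-binomial GLM
with log link, offsets = log effective library size, and design
[intercept, group, covariates…]; all genes share the design, so the
IRLS is vectorized across genes. Dispersion is estimated in two
passes: a near-Poisson fit provides means; a method-of-moments
estimate φ̂ = Σ((y−μ)² − μ)/μ² / (n − p) is computed per gene, clipped
to [10⁻⁶, 10], and shrunk toward a lowess trend over log mean
expression with prior weight 20 residual-df equivalents; the GLM is
refit at the shrunk dispersions and the group coefficient's Wald
statistic is referred to a t distribution with n − p degrees of
freedom. This mirrors the edgeR framework at the property level —
error control and power, not numerical identity, are the contract —
and the test suite cross-checks effect estimates against edgeR's
exactTest on a shared input (log-FC correlation > 0.95). Measured on
seeded null simulations (10 vs 10, 2000 genes) the raw p < 0.05
fraction is ≈ 0.04, and with 200 planted |log₂FC| = 2 genes
sensitivity is ≈ 1.0 at empirical FDR ≈ 0.01–0.03.

Thresholding keeps genes with |log₂FC| > 1 and BH-adjusted p < 0.05
(strict inequalities), ordered by |log₂FC| descending with gene-id
tie-breaks. An empty signature is legal and logged.

**Single-cell route.** Values are log(RSEM + 0.1) (natural log); genes
with variance < 0.1 across all cells are dropped; malignant vs
oligodendrocyte cells are compared by an equal-variance Student
t-test; log₂FC is the mean natural-log difference divided by ln 2 (the
base of the original computation is unstated; the conversion makes the
thresholds comparable with the bulk route). BH and the same thresholds
follow.

**Meta-signature.** The combination rule of the original analysis is
not described. The default is the direction-consistent intersection
with averaged log₂FC; union and average-then-rethreshold rules are
switchable. Genes up in one signature and down in the other are
excluded and logged under every rule.

## Reversal scoring

The enrichment score of a gene set at sorted 1-based positions
V(1) < … < V(t) in a ranking of n genes is

    a  = max_j ( j/t − V(j)/n )
    b  = max_j ( V(j)/n − (j−1)/t )
    ES = a  if a > b  else −b

which the test suite verifies against an exhaustive running-sum oracle
for every subset of universes up to size 12. Profile rankings order
genes by differential value descending with gene-id tie-breaks, making
scoring deterministic.

RGES = ES(up) − ES(down), zeroed when both scores share a sign — the
connectivity-map lineage convention, which the source summary does not
restate; it is on by default and switchable (`same_sign_zero=False`).
Up/down sets larger than 100 genes are truncated to the top 100 by
|log₂FC| (the truncation key is this package's reading of "top"
genes).

sRGES: the "simple statistics" used to summarize multiple profiles per
compound is not reproduced in the source, only its intent — referencing
scores to the 10 µM / 24 h condition. Implemented as one pooled OLS of
RGES on log₁₀(dose/10) and (duration − 24)/24 across all records,
whose fitted offsets are subtracted per record; adjusted scores are
then averaged within cell line and across cell lines. With metadata
absent the offsets are zero, and a config switch disables the
adjustment entirely. No cell-line weighting (e.g. favoring
brain-derived lines) is applied, as none is documented. The reversal
cutoff is sRGES < −0.1, strict.

## Evaluation

AC50 records must have both curve-quality flags strictly below 4.
Per-compound AC50 is the median across cell lines (robust,
monotone-preserving; the original aggregation is unstated), then
log₁₀-transformed; the Pearson correlation with sRGES is computed over
compounds passing the sRGES cutoff (a flag includes all overlapping
compounds), with a two-sided t-distribution p-value, and an error —
not NaN — below 3 compounds. Whether the original correlation used
AC50 or log AC50 is unstated; log is used because AC50s are lognormal
over orders of magnitude.

Target-class enrichment ranks compounds by sRGES ascending and applies
the same ES statistic per class, with a one-sided permutation p-value
over random same-size compound sets, +1-corrected on numerator and
denominator so p is never 0. Classes with < 2 ranked members, or all
members, are skipped.

The treatment reversal check ranks genes by treatment log₂FC and
computes ES(up) − ES(down) without the same-sign zeroing (the zeroing
convention exists to suppress non-reversal profiles in ranking tasks;
here a continuous statistic gives the permutation null full
resolution), with a one-sided permutation test toward reversal over
random gene sets of the same sizes. It requires ≥ 50% signature
coverage.

## Synthetic data: what it emulates, and what not

Counts are negative binomial in the mean/dispersion parameterization,
variance μ + φμ² with φ = 0.1 (typical bulk RNA-seq overdispersion).
Each tissue's mean profile is a shared lognormal baseline modulated by
N(0, 1) per-gene log₂ tissue effects; library sizes are uniform on
[1, 3]·10⁶; an optional batch factor multiplies a random 10% of genes
by 2^(strength · x) with x = ±0.5 per sample. Gene lengths are fixed
at 1 kb so TPM ∝ count/library-size and the count↔TPM conversion stays
trivial and testable. The disease cohort (default 22 samples,
mirroring the emulated study's cohort size) multiplies the source
tissue's means by 2^(log₂FC) on planted genes — effects uniform on
[1, 2.5] in magnitude by default, so some planted genes sit near the
detection threshold.

Drug profiles over the 978-landmark universe are −θ·log₂FC on
signature genes plus N(0, 0.3) noise everywhere, with θ modulated by a
dose/duration factor clamped to [0.25, 1.5], linear in log₁₀(dose/10)
and in duration/24 — giving the sRGES reference-condition correction
real structure to remove. The default panel has 100 compounds: 10
strong reversers (θ ≥ 0.75, launched, benign MOA classes, ≥ 4
profiles) and 90 weaker ones with mixed MOA classes (including the
excluded chemotherapy classes), phases and profile counts, so every
hit filter is exercised. AC50 (molar) = 10^(a − bθ + ε) with a = −4,
b = 2, ε ~ N(0, 0.25): θ = 1 corresponds to 1 µM potency. The
single-cell generator defaults to 2259 malignant and 232
oligodendrocyte cells with four disjoint program modules (cell cycle /
OPC-like / AC-like / OC-like) and dropout 0.3.

Not emulated: read-level sequencing noise, gene-length variation,
correlated gene modules within tissues (beyond the batch factor),
LINCS file formats, multi-study heterogeneity of the real compendium,
and the biological coupling between a drug's transcriptomic reversal
and its viability effect (the AC50 model imposes the monotone link by
construction). Passing tests therefore demonstrate that the machinery
recovers planted structure under the stated statistical model, not
that the biological signal in real data is this clean.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale: compendia of
800–2000 genes and a few hundred samples, autoencoder training at
reduced width/epochs (e.g. [128, 64] → 32, 20 epochs), 100-compound
libraries, and 99–200 permutation draws — sizes chosen so the full
suite completes in about a minute while leaving every statistical
property testable. The pipeline fans one global seed into per-stage
seeds via `SeedSequence([seed, stage_index])`, so stages are
independently reproducible and two runs with the same config are
byte-identical; every output TSV carries a header comment with the
config hash and seed.

## Known limitations

- The NB Wald test is approximate at very small sample sizes; below
  ~4 samples per group its calibration degrades (edgeR's exact or QL
  tests would be preferable there).
- The autoencoder is CPU-bound numpy; it is sized for 10²–10⁴ samples,
  not for very large compendia.
- sRGES dose/duration adjustment is a global linear correction; strong
  non-linear dose responses are only partially referenced.
- `combine_signatures` assumes the two signatures share a gene
  universe; no ortholog/id mapping is performed.
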