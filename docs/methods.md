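# Methods

This note documents the models implemented in `cellregvar`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Feature layout and expression models

A gene's regulatory context is a matrix of chromatin-feature predictions
over a TSS-centered window: `n_features` tracks (default 2002: histone
marks, TF binding, DNase hypersensitivity) by `n_bins` bins (window
half-width 20 kb, bin width 200 bp, hence 200 bins and 400,400 inputs per
gene). Bins are ordered 5'→3' along the annotated gene strand so that "bin
k" means the same TSS-relative position for genes on either strand. In
production these grids come from a pretrained sequence-to-chromatin CNN;
the package deliberately treats the predictor as a pluggable input (an HDF5
store of per-gene grids) and never touches raw sequence.

**Trainer.** Expression of one cell cluster is modeled as
`y = b + wᵀx` with `x` the flattened grid, fit by a boosted-linear
procedure under the gblinear hyperparameter contract: squared-error
objective, L2 penalty `lambda` (default 100), step shrinkage `eta`
(default 0.5), at most 40 rounds, early stopping after 10 rounds without
validation improvement. Each round moves the weights a fraction `eta`
toward the closed-form L2-penalized least-squares solution (intercept
unpenalized):

    w ← w + eta · (w_ridge − w)

This update has the same fixed point as coordinate-descent gblinear and
makes the trainer exactly oracle-checkable: with `eta = 1` and one round it
*is* ridge regression, which the tests verify against the normal equations.
An optional backend (`train_with_backend`) runs true xgboost gblinear and
is used in the test suite as an independent cross-check (holdout PCCs agree
within 0.01); the native implementation is always the reference path.

**Validation split.** Early stopping uses a seeded random 10% of the
*training* genes. The chromosome holdout (chr8 by default, accepting both
"8" and "chr8" spellings) is never used for early stopping — using the test
chromosome to tune stopping would leak information into the reported
holdout correlation, so the trainer refuses to do it.

**Evaluation.** Pearson correlation between predicted and observed log
expression on holdout genes; zero-variance vectors yield a missing value
rather than a number. Cell-type specificity of the models is evaluated by
the log fold change of the focal cluster against the mean over clusters,
for predictions and observations, correlated across holdout genes.

## In-silico mutagenesis and specificity

The variant delta is the elementwise alt−ref difference of feature grids,
flattened in layout order; only biallelic SNVs are accepted. The
per-cluster effect is `wᵀΔ` with the intercept excluded, so a null delta
has exactly zero effect and the quantity equals the prediction difference
of a linear model.

Cell-type specificity uses a one-tailed Welch (unequal-variance) t-test on
absolute effects, clusters of the focal cell type versus all other
clusters, with Welch–Satterthwaite degrees of freedom. When a focal cell
type has a single cluster the test degenerates; the implementation falls
back to a z-score of the focal |effect| against the other-cluster
distribution and flags the result approximate. Functional variant sets are
formed by requiring max |effect| in focal clusters above a floor (default
0.5), ranking by ascending one-sided p (ties: larger t, then variant id),
and truncating to `top_k` (default 2000).

Note on calibration: with a handful of clusters per group the Welch test on
folded-normal absolute effects is slightly *conservative* (null rejection
below nominal). The test suite asserts validity (type-I error not above the
binomial band) rather than exact uniformity of the null p-values, which is
the property that matters for selection.

The cluster-vs-tissue contrast assigns category 2 to variants whose
|cluster effect| exceeds |tissue effect| by more than 1.96 standard
deviations of that difference, the SD computed across all variants of the
tissue — the natural reference population when one tissue model is
compared to its clusters.

## Interaction-eQTL mapping

Expression screening keeps genes with TPM ≥ 0.1 in ≥ 20% of samples and
raw counts ≥ 6 in ≥ 20% of samples (both bounds inclusive). Counts are
TMM-normalized — trimmed mean of M-values with 30% log-ratio trim, 5%
absolute-expression trim, precision weighting, reference sample chosen by
closest upper quartile, factors rescaled to geometric mean 1; the
implementation reproduces edgeR's factors to ~1e-6 on random fixtures and
is cross-checked against edgeR in the test suite. Expression and
cell-fraction estimates are then rank-transformed to normal quantiles
(Φ⁻¹((rank−0.5)/n), average ranks for ties, all-tied vectors mapping
to zero). Cell clusters are retained when their absolute deconvolution
score exceeds 1 in strictly more than a fifth of samples.

The interaction model is OLS on the design `[1, g, f, g·f, C]`; the
reported p-value is the two-sided t-test of the g·f coefficient with
`n − rank` degrees of freedom. Rank-deficient designs raise an error naming
the offending columns. Cis windows are closed intervals ±1 Mb around the
TSS (positions 1-based as in VCF), with MAF computed from dosages as
`min(mean/2, 1 − mean/2)` and filtered at 0.05. The top variant per gene is
the smallest interaction p (ties: larger |t|, then smaller position).

Multiple testing follows the two-stage convention: the top p is multiplied
by the effective number of independent cis variants — eigen-decomposition
of the variant correlation matrix in consecutive windows of 200 variants,
counting eigenvalues needed to reach 99% of the trace, summed and capped at
the variant count — then Benjamini–Hochberg adjusted across genes. The
window size and variance fraction are the defaults of the eigenvalue-based
correction this emulates.

Negatively correlated ieQTLs — signals that likely originate in *other*
cell types — are flagged by splitting samples into fraction quartiles,
fitting `y ~ g (+C)` per bin, and requiring a consistent sign of the
genotype effect with |effect| in the top bin below the bottom bin.
Quartiles with the extreme-bin comparison are this package's choice; at
least 10 samples per bin are required, otherwise the flag is undetermined.

## LD integration

LD is the squared Pearson correlation of dosage vectors (composite LD, as
computed on unphased data by standard tooling); missing dosages are
mean-imputed per variant and constant variants yield missing r². A
functional variant is linked to a gene when it is in r² > 0.8 (strict) with
a candidate top (i)eQTL at FDR < 0.4 (strict). The relaxed FDR is
deliberate: genome-wide BH is conservative when many genes truly have
QTLs, and the requirement of an independent predicted effect > 0.5 in LD
controls false positives at the pair level. LD blocks for the
prediction-vs-eQTL benchmark are single-linkage connected components grown
from the top eQTL variant at r² > 0.6. The fine-mapping benchmark samples
one LD-linked (r² > 0.6) low-PIP (< 0.01) negative per fine-mapped
positive, seeded, and scores a single-feature logistic classifier by AUROC.

## Colocalization, credible sets, variant-to-function

Per-variant evidence is the Wakefield log approximate Bayes factor:
`0.5·log(1−r) + 0.5·z²·r` with `z = β/se`, `V = se²`, `r = W/(V+W)`. Prior
effect variances default to 0.15² for quantitative traits and 0.2² for
case-control (the conventional defaults); configuration priors are
p1 = p2 = 1e-4, p12 = 1e-5. Posteriors over the five causal configurations
are accumulated in log space and agree with exhaustive enumeration to 1e-9
on small instances (a test asserts this). Genes are tested only when their
top nominal association is below 1e-5; PP.H4 > 0.85 (strict) counts as
positive colocalization.

Fine-mapping defaults to the single-causal ABF approximation:
PIP_i = ABF_i / ΣABF, credible set = minimal PIP-descending prefix with
cumulative PIP ≥ 0.95. Externally computed PIPs (e.g. from a
sum-of-single-effects fine-mapper) can be supplied via a `pip` column and
take precedence. GWAS regions are 100 kb windows centered on lead variants
of p < 1e-5 loci after greedy non-overlap clumping by ascending p.
Variant-to-function mapping emits a record when a functional variant lies
inside such a region *and* is a member of its 95% credible set.

The GWAS-label classifier treats p < 5e-8 as positive and p > 0.05 as
negative and requires more than 20 positives (i.e. ≥ 21) per trait.
Heritability-annotation output writes per-chromosome tables (CHR, BP, SNP,
CM, a base all-ones column, one binary column per cell type set); the
regression itself is out of scope, only the file contract is honored. The
signed-log enrichment display transform is a plotting convenience, not an
inferential statistic.

## Enrichment statistics

- **Matched nulls**: one pool variant per target, matched on the requested
  strata (chromosome, MAF bin, TSS-distance bin), drawn with replacement
  across sets; empty strata are an error naming the stratum.
- **Fold difference**: mean |target| over mean |pooled null|; the 95% CI
  comes from 10,000 bootstrap resamples *of the null sets* with the target
  set held fixed — the CI therefore quantifies null-construction
  uncertainty conditional on the observed targets, which is what the
  calibration test checks.
- **Permutation enrichment**: unweighted KS-like running-sum maximum
  deviation of the hit set in the ranked list; permutations are uniform
  same-size draws; `p = (1 + #{perm ≥ obs})/(n_perm + 1)` (never zero);
  NES = observed / mean(permuted).
- **Fisher enrichment**: exact hypergeometric p always; odds ratio with a
  Haldane 0.5 correction (flagged) when a cell is zero.
- **Recovery AUC**: area of the cumulative-recovery curve over the top 5%
  (configurable) of the ranking, normalized by the best achievable area, so
  the score lies in [0, 1]. Grids of AUC scores are row z-scored
  (constant rows become zeros and are flagged) and ordered by Ward-variance
  hierarchical clustering with deterministic optimal leaf ordering.

## Synthetic-data generators

All generators are pure functions of (parameters, seed); one global seed
fans out to independent child streams by fixed offsets.

- **Feature grids**: rank-`r` mixtures of shared patterns plus Gaussian
  noise — enough structure for a linear model to learn, with controllable
  SNR. They do not emulate the value distribution, sparsity, or
  inter-track correlation of real chromatin predictions.
- **Expression**: exactly linear in the flattened grid plus noise, so
  trainer recovery has a known optimum; real expression is of course not
  linear in chromatin features.
- **Genotypes**: dosages in {0,1,2}; within an LD block each variant copies
  its neighbor per sample with probability `copy_prob`, otherwise redraws
  binomially at the block MAF, giving r² that decays with distance. This
  produces the r² structure the thresholds need but not realistic human
  haplotypes, allele-frequency spectra, or recombination maps.
- **Cohorts**: fractions drawn log-normal and passed through the same
  inverse normal transform the mapper applies (so planted coefficients are
  exactly identifiable at zero noise); phenotype
  `y = β1·g·f + β2·g + β3·f + Cγ + ε`.
- **Variant deltas**: a planted fraction of variants carries
  `effect_size` times the unit mean-weight direction of one cell type's
  clusters on top of isotropic noise; only that cell type's models project
  a large effect.
- **GWAS summaries**: marginal effects proportional to LD with one planted
  causal variant, with sampling noise at `se = 1/√N`.

**Pipeline fixture scale.** The end-to-end toy pipeline defaults to 120
genes (6 features × 10 bins), 8 clusters in 4 cell types, 150 samples, 60
variants in blocks of 4, and 6 ieQTL genes — small enough to run in about a
second while exercising every stage. Three fixture choices implement the
"strong planted signal" regime under which end-to-end recovery is asserted:
the planted delta effect is 6.0 (fitted weights are ridge-shrunk, so raw
effects must clear the 0.5 selection floor with margin), planted ieQTL
causal variants are restricted to MAF ≥ 0.2 (adequate interaction-test
power at 150 samples), and the within-block copy probability is 0.99 (so
top-variant vs causal-variant LD links are unambiguous at the 0.8
threshold). Passing recovery tests under these conditions demonstrates the
machinery is correct; it says nothing about power on real data at
realistic effect sizes.

## Numerical conventions and degenerate inputs

Internal coordinates are 0-based half-open; VCF positions convert at the
boundary; phenotype BED rows place the TSS at the `end` coordinate. Ties
are always broken deterministically (documented per operation), so rerunning
any stage with the same seed reproduces byte-identical text outputs.
Zero-variance vectors yield missing statistics rather than exceptions where
a missing value is meaningful (PCC, LD with a constant variant) and
errors where silence would corrupt downstream results (rank-deficient
designs, empty colocalization intersections, empty permutation hit sets).

## Known limitations

- The chromatin predictor is an interface, not an implementation: nothing
  here computes features from sequence, and grid fidelity is entirely the
  caller's responsibility.
- Single-causal ABF fine-mapping ignores multiple causal variants and LD
  between them; supply external PIPs for anything beyond one signal per
  region.
- Composite-LD r² on dosages differs from haplotype r² when phasing
  matters; no phasing is attempted.
- Deconvolution, covariate (PEER/PC) estimation, and single-cell
  imputation are consumed as inputs, never computed.
- The boosted-linear trainer is linear by construction; it cannot capture
  interactions between chromatin features that a tree booster might.
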