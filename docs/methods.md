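# Methods

This note documents the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical and design decisions that were
genuinely open.

## Genotype model and filtering

Genotypes are diploid alternate-allele dosages {0, 1, 2} with a
missing code (internally −1, on disk configurable, default 9).  The
per-SNP allele frequency p̂ is always computed over typed calls only:
with missing data there is no other defensible denominator.

The capture-style filters run in a fixed order — quality < threshold
(default 40), copy number ≠ 1, minor allele count < 3, call rate
< 60%, observed heterozygotes exceeding the Hardy–Weinberg expectation
2·n_typed·p̂(1−p̂) by more than 10 — and the report attributes each
removed SNP to the first rule it fails.  Each rule can be disabled
independently.  Copy number is an annotation column, not computed
here.  Filtering is idempotent by construction: surviving SNPs pass
every active rule.

Monomorphic SNPs cannot be standardized (zero variance); they are
removed by the minor-allele-count rule when it is active, and
standardization raises a named error if one slips through.

## The PCA-loading scan

Standardization uses the drift-scale normalization
(g − 2p̂)/√(2p̂(1−p̂)); missing entries are set to zero after
centring, i.e. mean imputation.  Mean imputation biases loadings
toward zero for high-missingness SNPs — conservative for outlier
detection — and is the only imputation offered; probabilistic
imputation would add a model the test does not need.

PCA is a plain SVD of the standardized matrix.  Scores are left
singular vectors scaled by singular values; the eigenvalues reported
are singular values squared over (n−1).  Component signs are fixed so
the largest-magnitude score entry is positive, making score thresholds
(e.g. the 0.1 unit-norm cutoff used to peel off a hyper-diverged
cluster) reproducible across runs and platforms.  The scree table
reports an advisory elbow (largest consecutive eigenvalue drop ratio),
but K is always the caller's choice — the elbow of a real panel is a
judgement call.

The test statistic is the loading ρ_jk, the Pearson correlation
between a SNP's standardized genotypes and the component scores,
computed over typed entries only.  The null center and scale per
component are the median and MAD/0.67449 of the loadings.  The robust
pair is used rather than mean/SD because the quantities being tested —
outliers — would otherwise inflate their own null scale; the
normal-consistency constant makes the scale estimate unbiased for a
Gaussian bulk.  p-values are two-sided (a divergence axis has no
privileged direction); q-values are Benjamini–Hochberg within each
component by default, with Storey's π₀-adjusted variant behind a flag
(the two differ only by the π₀ factor, and BH is the conservative
choice).

The global test sums z² across components (identity covariance: the
robustly standardized component statistics are uncorrelated by
construction of the PCs), rescales by the genomic inflation factor
λ = median(D²)/χ²_{K,0.5}, and refers D²/λ to χ²_K.  λ absorbs any
global miscalibration of the per-component scales; under an i.i.d.
normal null λ ≈ 1 and D²/λ matches χ²_K to KS distance < 0.01 at 10⁴
SNPs (checked by test).  A minimum-covariance-determinant estimate of
the z covariance is available (`covariance="mcd"`) for panels where
components are correlated after robust standardization; on clean nulls
the two orderings agree (rank correlation > 0.95).

Known limitation: the robust null absorbs *background* differentiation
as well as noise.  Between two races with drift F, all loci differ a
little, so the null MAD grows with F and the scan's resolution for a
planted frequency shift shrinks as background divergence rises.  This
is intrinsic to the loading statistic, not an implementation artifact;
it is why power guarantees below are stated at low background drift.

## Gene and category tests

With panel outlier proportion π (at q ≤ 0.05 in a chosen scope — one
component, the global test, or "any component"), a gene with n_g SNPs
and o_g outliers gets the right-tail Poisson probability
P(X ≥ o_g), X ~ Poisson(n_g·π).  The discreteness of the test makes
it sub-nominal (< 7% of genes flagged at p < 0.05 under a random-flag
null in simulation), i.e. the gene list is conservative.  An optional
minimum-outlier-count gate (e.g. ≥ 3 outlier SNPs) reproduces the
stricter convention used in earlier candidate-gene work.  The outlier
threshold is configurable because "outlier" can reasonably mean q ≤
0.05 or p ≤ 0.05; the default is the q-based reading.  No multiplicity
correction is applied across genes by default (a BH option exists);
genes are tested wherever they have at least one SNP.  Promoter
regions annotated as their own gene IDs are simply tested as genes.

Category contrasts use the pooled two-proportion z-test
z = (p̂_B − p̂_A)/√(p̄(1−p̄)(1/n_A + 1/n_B)), two-sided by default
with one-sided alternatives exposed.  A degenerate pooled proportion
(0 or 1) yields p = 1 with a warning rather than an error: an
all-null or all-outlier panel is uninformative, not invalid.

## Hierarchical AMOVA

The three-level decomposition (among groups = races; among populations
within groups = localities within race; within populations) operates
on gene copies: each typed diploid contributes two 0/1 allele
indicators.  Because the indicator is 0/1, every sum of squares
reduces to a closed form in per-population allele counts, so the
locus-by-locus analysis and its permutations are fully vectorized.
Variance components are solved from the expected mean squares of the
unbalanced nested design (the standard coefficients weighted by
gene-copy counts); a within-individual level is deliberately omitted —
the decomposition matches the two structured percentages plus residual
that the race/locality design calls for.  Negative variance components
are reported as computed, never truncated, and percentages use the
signed sums.  Monomorphic loci get all-zero components and a flag.

Aggregate percentages come from components summed across loci (the
weighted-average convention); the per-category summary instead takes
unweighted per-locus means of the percentage components, the natural
scale for comparing gene categories of different sizes.

Significance is by permutation: whole populations are permuted among
groups for the among-group component, individuals among populations
within their group for the among-population component, with
p = (1 + #{perm ≥ obs})/(1 + n_perm).  When the design admits fewer
distinct among-group assignments than n_perm, the null is enumerated
exhaustively and p becomes exact.  On tiny designs the achievable p is
bounded by ties: with three groups of two populations each, every
relabelling that keeps the dominant race's populations together
reproduces the observed statistic, so p cannot drop below that tie
fraction — a property of the design, not a defect of the test.

## Migrant reassignment and hybrid pruning

Samples are assigned to genetic clusters from their PCA scores,
anchored at the collection host: per-host centroids are score medians
(robust to the few mislabelled individuals being sought), axes are
globally standardized, and each sample is projected onto the segment
from its host's centroid to the nearest other centroid.  The
projection fraction t is ~0 for residents, ~0.5 for F1 hybrids and ~1
for migrants.  Decision rules, all configurable:

* **hybrid** (removed): max-over-axes projection t in [0.25, 0.75]
  *and* per-sample heterozygosity more than 1 robust SD above the host
  cluster's median.  Position alone proved unreliable in simulation —
  PCA score shrinkage pulls F1s toward their host centroid and 3-SD
  per-axis fluctuations false-flag residents — while first-generation
  hybrids between diverged races carry a crisp heterozygosity excess;
  requiring both separates residents, hybrids and migrants with no
  overlap across replicate panels at F_race ≥ 0.2.  The max over
  well-separated axes finds the parent cluster even when it is not the
  nearest centroid.  Without genotype data (scores only) the rule
  falls back to position plus distance from both centroids.
* **migrant** (relabelled to the other cluster's host): t past the
  midpoint *and* displacement from the host centroid exceeding 3
  robust SDs.  The significance gate matters between weakly separated
  clusters, where projection noise alone would relabel residents.
* **ambiguous** (left unchanged, warned): cluster pairs separated by
  fewer than 3 within-cluster SDs, or displacement without a clear
  class.

## Cross-panel concordance

SNPs are matched by exact ID.  Axes are paired by maximizing the
Pearson correlation of *squared* loadings over shared SNPs (squaring
removes the arbitrary sign and emphasizes the outlier tail); pairing
may be many-to-one since two panels need not resolve the same axes.
The summary correlations are the per-paired-axis r and the r between
per-SNP maxima of squared loadings across axes.

The overlap test asks whether the number of SNPs significant in both
panels exceeds chance: panel B's significant count is re-assigned
uniformly without replacement over *all* of panel B's SNPs (unshared
positions contribute zero overlap), and p = (1 + #{perm ≥ obs})/(1 +
n_perm) — the add-one rule keeps p above 1/(1+n_perm).  For small
configurations the permutation p converges to the hypergeometric tail,
which the tests verify exhaustively for panels of up to 8 SNPs.
"Significant in A" defaults to q ≤ 0.05 on at least one component,
with a global-only option.

## The synthetic generator

Allele frequencies follow the Balding–Nichols model: ancestral
p ~ U(0.05, 0.95); each race's frequency ~ Beta(p(1−F_r)/F_r,
(1−p)(1−F_r)/F_r); locality frequencies are drawn the same way around
their race frequency with F_loc.  F = 0 degenerates to a point mass.
The Beta model was chosen over a coalescent because the analysis only
ever sees frequencies, the moments are analytic (e.g.
E[(f_A−f_B)²/(p(1−p))] = 2F, used as a generator oracle in tests), and
it is fast.

Defaults mirror the study conditions the package is designed for:
eight races on a divergence continuum with F_race from 0.8 (a
hyper-diverged race that dominates PC1 and exercises the
exclude-and-rerun path) down to 0.02 (the most closely related pair,
matching multilocus F_ST of roughly 0.02–0.08); locality drift
F_loc = 0.02, an order of magnitude below race-level divergence; two
localities per race and seven diploids per locality (~112 samples, the
scale of a capture panel); genes in three categories (chemosensory /
control / P450) with five SNPs per gene.  Selected loci are planted as
frequency shifts — the two target races move to ancestral ± δ/2,
recentred where clipping to [0.01, 0.99] would otherwise shrink the
separation, so δ is exactly the realized |f_A − f_B| — clustered
several SNPs to a gene in the chemosensory category to mimic multi-SNP
outlier genes.  By default the planted pair is the two least-drifted
races: selection signal on a low-drift background is the regime the
scan is designed to detect.  Migrants keep their collection-host label
but draw their genotype from another race; F1 hybrids draw one allele
from each parental race; calls go missing independently.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: linkage disequilibrium between SNPs
(loci are independent given frequencies), genealogical noise and
shared drift beyond the Beta hierarchy, allele-frequency-dependent
genotyping error or dropout, clonal structure or repeated genotypes,
temporal structure in the year labels, and selection as a dynamic
process (only its frequency footprint is modelled).

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use scaled panels
chosen to make each property measurable with headroom: 5 000 SNPs for
null-uniformity KS checks, 10⁴ SNPs for the Mahalanobis calibration,
500 loci for Φ_CT recovery (±0.05), 100 diploids and 500 SNPs per
replicate (10 replicates, pooled counts) for planted-outlier power and
FDR at separation 0.5, twenty ~64-sample panels for migrant/hybrid
accuracy, and 10⁵ permutations for overlap tests.  Permutation
p-values use a 10⁻¹² tie tolerance; robust scales are floored at 10⁻⁹;
BH q-values use statsmodels' implementation.  All stochastic code
takes explicit seeds; the scan itself is deterministic, including
component signs.
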