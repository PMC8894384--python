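# Methods

## Model and assumptions

The package tests, per gene, the null hypothesis that none of its M
variants is associated with the trait, using only summary-level inputs:
the vector of per-variant Z-scores, an LD correlation matrix R, and K
eQTL-derived diagonal weight sets. The working assumption is the standard
summary-statistic one: under the null, Z ~ MVN(0, R), with R estimable
from a reference panel of the same population as the GWAS. All downstream
nulls are exact consequences of this multivariate-normal assumption; no
permutation or individual-level data is used anywhere.

Mis-estimated LD is the main threat to validity. A reference panel of a
few hundred samples adds noise to R that inflates quadratic-form tests,
so R is corrected by shrinkage toward the identity, U = aR + (1-a)I,
with a chosen to maximize the MVN(0, U) likelihood of the observed Z.
Because U shares R's eigenvectors, the likelihood is optimized in R's
eigenbasis (a one-dimensional problem; 21-point grid scan plus
golden-section refinement, tolerance 1e-4 on a, ties broken toward a = 1
so that an exact LD matrix is never shrunk). When R is singular and
a = 1, a ridge of 1e-10 is applied to the likelihood evaluation only.
When R is in fact the exact covariance of Z — as in the type-I
simulations, where Z is drawn from R itself — the truth is a = 1 and the
refit only adds noise; the type-I driver therefore runs with the
shrinkage inert by default and exposes `refit_a=True` to quantify the
inflation the refit would cause (see "Design choices" below). For real
data, where R is noisy, the per-gene refit is the default throughout.

## Test statistics and their nulls

Raw weights are standardized to unit absolute sum per study, so only the
relative pattern and signs matter; the k = 0 set is all ones. For each
weight set:

* **Burden**: Q = (Z' W 1)²; Q / (1'WUW1) is 1-df chi-square under the
  null. The variance scaling is required for the 1-df reference to hold
  and is applied always.
* **SKAT**: Q = (WZ)'(WZ); the null is sum_i lambda_i chi2_1 with
  lambda_i the eigenvalues of Sigma = WUW (eigenvalues below
  1e-10 x max are dropped).
* **SKAT-O**: Q_rho = (1-rho)Q_SKAT + rho Q_BT minimized over the grid
  rho in {0, 0.1², ..., 0.9², 1} (the canonical grid; configurable). The
  minimum per-rho p-value T is calibrated exactly: conditional on the
  burden chi-square component x, the residual of every Q_rho is one and
  the same noncentral weighted chi-square form (complete-the-square in
  the subspace orthogonal to the burden direction), so
  P(min_rho p_rho > T) is a one-dimensional integral of a noncentral
  quadratic-form CDF against the chi2_1 density. No moment-matching
  approximation is involved; the result is clipped to its analytic
  envelope [T, min(1, |grid| T)]. A grid with a single point reduces to
  the corresponding endpoint test, as does M = 1.

### Quadratic-form tail probabilities

P(sum lambda_i chi2_1 > q) is computed by numerical inversion of the
Laplace transform of the survival function on a fixed Talbot contour
(32 nodes; all branch points of the transform lie on the negative real
axis). Verified absolute accuracy is ~5e-10 in the central region.
Two regimes get dedicated branches: q << E[Q] uses Ruben's
mixture-of-central-chi-squares series (with an early bail-out when the
eigenvalue spread makes its geometric convergence hopeless), and deep
tails (p < 1e-7) use the Lugannani-Rice saddlepoint, which is relatively
accurate exactly where the contour sum's absolute error floor would
dominate. Equal eigenvalues short-circuit to the exact scaled chi-square.
A Liu-type four-cumulant approximation remains as a logged fallback for
reported failures; p-values are floored at 1e-300. The noncentral variant
of the same contour inversion serves the SKAT-O conditional integral.

In the replication loops (Omega estimation, type-I and power drivers),
SKAT-O drops to a coarse tier (fewer quadrature nodes and panels, looser
quantile tolerance) whenever its min-p statistic exceeds 0.02; measured
coarse-vs-fine discrepancy is below 5e-4, far from the 0.01 and 1.75e-6
thresholds at which rejections are counted. The public `skato_test`
always uses the fine tier. Threshold quantiles q_rho(T) are found by
safeguarded Newton on the log survival function; only thresholds whose
affine section can touch the lower envelope of the conditional constraint
are inverted exactly (the argmin rho's threshold is its observed
statistic, which needs no inversion).

## The Overall combination and Omega

The L = 3(K+1) p-values are combined as
p_overall = min_l m_e p_(l) / m_e(l), where m_e(l) is the effective
number of tests among the l smallest p-values: l minus the excess above
one of each eigenvalue of the corresponding submatrix of Omega, the null
correlation matrix of the p-values. "Top l" means the l smallest
p-values, with ties broken by the canonical label order (BT, SKAT,
SKATO per weight set, k = 0..K); the minimum is capped at 1. Negative
eigenvalues of noisy sample submatrices are clipped at zero (logged);
this cannot change m_e(l), which only sums eigenvalue excesses above one,
but guards the invariant 1 <= m_e(l) <= l.

Omega is estimated once per gene: B = 1000 replications (the default,
following the convergence analysis reproduced by `omega_convergence`,
which replaces a model-fit equality test with max-absolute and Frobenius
distances to a large-B reference computed on a shared replicate stream)
of Z ~ MVN(0, R) — R, not U, since that is the distribution the null
Z-scores are actually generated from — each rerun through the full
battery including the shrinkage refit, followed by the Pearson sample
correlation of the raw p-value columns (no rank or quantile transform).
Replicates with isolated numerical failures (at most 5%) are dropped;
persistently failing tests lose their column with a warning and the
drivers align the battery to the surviving labels.

## Comparators

OT transforms each of the L p-values by tan((0.5 - p) pi), averages, and
maps back through the standard Cauchy distribution; inputs are clipped
into [1e-15, 1 - 1e-15] to keep the tangent finite. S-TWAS is
w'Z / sqrt(w'Rw) against N(0, 1); S-PrediXcan additionally scales by
per-SNP genotype standard deviations and the predicted-expression SD, and
coincides with S-TWAS when genotypes are standardized (the default). Both
use R rather than U, following their published definitions; a flag
substitutes U.

## Synthetic data

The generator emulates a TWAS-style simulation design. A haplotype pool
stands in for a reference panel: latent Gaussian vectors with AR(1)
correlation (rho = 0.7 by default) are thresholded at each variant's
target allele-frequency quantile, yielding binary haplotypes whose dosage
LD decays with distance; defaults (M = 23 variants, 458 haplotypes)
mirror a small-gene setting. Genotypes sum two haplotypes drawn with
replacement by pool frequency; variants with sample MAF < 0.05 are
removed and all downstream objects subset consistently. Per expression
study, a causal subset of size round(M p_causal) (minimum 1) gets
standard-normal weights, rescaled so the sample variance of Xw equals the
expression heritability h_e² exactly; expression adds N(0, 1 - h_e²)
noise. The phenotype is Y = E beta + N(0, 1 - h_p²) with per-study
effects beta_0 = sqrt(h_p²/K) arranged uni- or bi-directionally, the
bi split giving the first half of the studies +beta_0 and the rest
-beta_0; the tissue-relevance noise scenarios (K = 4 only) perturb the
designated relevant studies by N(0, 0.1 h_p²) and the others by
N(0, 0.5 h_p²). Z-scores are the per-variant OLS t-statistics of Y on
dosage (capped at ±1e8 for degenerate fits; constant columns dropped).

What this emulation does not capture: real LD block structure and rare
variants of reference haplotypes, estimation noise in real eQTL weights
(the analysis weights are the generative truth), cross-tissue correlation
of weights (causal sets are drawn independently per study), covariates
and population stratification, and case-control phenotypes. Passing
tests therefore demonstrate the statistical machinery — calibration,
exactness of nulls, the value of combining tests — under a controlled
generative model, not performance on any particular real gene.

## Experiment drivers

The type-I driver draws null Z directly from R, computes the full battery
per replicate, and reports empirical rejection rates with binomial
standard errors; Omega is estimated once before the rate loop. The power
driver generates full cohorts per replicate — fresh causal sets, weights,
expression and phenotype — computes Z-scores, estimates LD from the
cohort's own genotypes (a mismatched panel can be injected, and
shrinkage can be disabled, to reproduce corrected-vs-uncorrected LD
comparisons), analyzes with the cohort's true weights, and reports the
proportion of replicates with p < 1.75e-6 (0.05/28625, the gene-based
Bonferroni threshold). BEST is the per-cell maximum power over the
battery; S-TWAS.B and S-PrediXcan.B the maxima over single-weight tests —
reporting conventions, not statistics. Omega is estimated once per cell
from a reference cohort (the once-per-gene design); cells differing only
in h_p² or direction scenario share the reference architecture via a
derived seed so their powers are comparable along those axes.

## Design choices where the design was open

* **Type-I shrinkage default.** With Z drawn from R itself the shrinkage
  truth is a = 1, and refitting â from each simulated Z leaves a < 1
  often enough on a well-conditioned AR(1) matrix to make the burden test
  mildly anti-conservative, whereas with a near-singular real LD matrix
  the likelihood pins â at 1 and the refit is inert. The driver defaults
  to the inert setting (the truth under its own generative model) and
  exposes the refit for studying exactly that inflation. Real-data
  analysis (`run_gene`) and Omega estimation keep the per-gene refit.
* **Per-replicate architecture in the power driver.** Each replicate
  redraws causal sets and weights, and analyzes with that replicate's
  true weights; the fixed per-cell Omega is thus an approximation
  (exact Omega would have to be re-estimated per replicate). A
  `fix_weights` flag freezes the reference architecture instead, which
  makes Omega exact for the cell at the cost of conditioning all power
  statements on one architecture draw.
* **Strand-ambiguous variants** (A/T, C/G) are dropped during
  harmonization rather than resolved by frequency, and duplicated IDs
  are dropped entirely; allele swaps flip the Z sign.
* **Numerical tolerances**: LD symmetry 1e-6 on read, unit diagonal
  1e-8; eigenvalue truncation 1e-10 x max for test nulls and
  1e-12 x max for the SKAT-O conditional decomposition; weight
  standardization exact to 1e-12; Omega entries symmetrized and clipped
  to [-1, 1] with unit diagonal forced.

## Problem sizes used by the shipped studies

The calibration study in the test suite uses a 23-variant AR(1)(0.5)
gene with four random weight studies, Omega at B = 1000, and 5x10^4 null
replicates; oracle checks use 10^6-draw Monte-Carlo references; the power
study uses 200 replicates per cell over h_p² in {0, 0.1, 0.2} for both
direction scenarios at n = 2000; heritability recovery uses n = 10^5.

## Known limitations

Covariate adjustment, binary phenotypes, small-sample SKAT corrections,
MAF-based variant weighting, multi-tissue joint models, and training of
expression predictors are out of scope. The conditional SKAT-O
integration assumes the burden direction carries positive variance; when
1'Sigma1 is numerically zero the test falls back to its Bonferroni
envelope. The Cauchy combination is slightly anti-conservative at
non-extreme significance levels, a known property of the transform
rather than of this implementation.
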