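# Methods

## Model

For a phenotype vector **y** over n individuals, a variant dosage
**X**_r, and an environmental exposure **D** (binary 0/1 or continuous),
the per-variant interaction model is

    y = mu + beta_r X_r + delta D + gamma_r (D . X_r) + u + v + e

with fixed effects mu, beta_r (SNP main effect), delta (exposure main
effect) and gamma_r (gene-by-environment interaction, GxE), and random
effects

    var(u) = sigma_g^2 K,   var(v) = sigma_d^2 K^D,   var(e) = sigma_e^2 I,

so that var(y) = Sigma = sigma_g^2 K + sigma_d^2 K^D + sigma_e^2 I.
K is the standardized-genotype genetic relationship matrix

    K_ij = (1/m) sum_s (x_is - 2 p_s)(x_js - 2 p_s) / (2 p_s (1 - p_s)),

and K^D restricts relatedness to pairs sharing an environment: for
binary D, K^D_ij = K_ij if D_i = D_j and 0 otherwise; for continuous D,
K^D_ij = K_ij f(D_i, D_j) with a similarity kernel f in [0, 1],
f(d, d) = 1 (range-scaled: f = 1 - |D_i - D_j|/R; normal-CDF:
f = 1 - |Phi(z_i) - Phi(z_j)| on standardized exposures). Which kernel
is appropriate depends on the scale of the exposure; neither is
asserted as a universal default and both are exposed.

The rationale: under a polygenic model with many small SNP and GxE
effects, the residual of a single-variant regression contains the
other variants' effects. Genetically related individuals share the
polygenic part (inflating SNP statistics) and related individuals in
the *same environment* additionally share the polygenic-by-environment
part (inflating GxE statistics). A mixed model with K alone absorbs the
first term only; adding K^D absorbs the second.

Four scan modes are provided: `ols` (Sigma = I, no correction),
`one_re` (K only), `two_re` (K and K^D), and `pc_x_env` (OLS with top
kinship eigenvectors and their products with D as fixed covariates, the
EIGENSTRAT-style comparator; a flag selects whether the PCs come from
the genetic or the GxE kinship, since both variants are in use).

## Variance-component estimation

Components are estimated by restricted maximum likelihood using the
average-information (AI) algorithm with one initial EM step, starting
from an equal split of the phenotypic variance and iterating until the
restricted log-likelihood changes by less than 1e-6 and the free
gradient norm falls below 1e-4 (at most 50 iterations; non-convergence
is flagged on the result rather than raised). Negative proposals are
clamped to 1e-6 x var(y) and flagged as boundary estimates; clamped
components with an inward-pointing gradient are held fixed and the AI
system is solved on the remaining ("active-set") coordinates. Every
step passes a backtracking line search on the restricted likelihood; if
the AI direction cannot improve it the monotone EM update is used, and
if neither can, the point is declared stationary. Standard errors come
from the inverse AI matrix at the optimum, and variance fractions
sigma_k^2 / sum sigma^2 carry delta-method standard errors.

The null fixed-effect design contains an intercept, the exposure D and
any user covariates — not the tested variant: components are estimated
once per phenotype and reused for every variant (the EMMAX strategy),
with a flag to drop D for study designs where it is not wanted as a
fixed effect. With a single kinship the problem is rotated by the
eigenvectors of K once so that every iteration costs O(n p^2); with two
kinships no simultaneous diagonalization exists and each iteration uses
dense Cholesky factorizations, O(n^3).

## Association testing

For each variant, coefficients are the GLS solution
(X' Sigma^-1 X)^-1 X' Sigma^-1 y with the fitted Sigma. The scan
Cholesky-factors Sigma once, whitens y and the shared covariates by a
triangular solve, and streams variants through vectorized normal
equations; `test_variant` on a single column produces the same numbers.
Each of beta_r and gamma_r is tested marginally (from the full
interaction model) with a 1-df F statistic (coef/SE)^2 against
F(1, n - p), where p counts all fixed-effect columns: at GWAS sample
sizes this is indistinguishable from a chi-square test, at toy sizes it
is exact under normality and testable. A joint 2-df F test of
(beta_r, gamma_r) is reported as an extra column but is not used in the
inflation diagnostics, which treat SNP and GxE families separately.

Rank-deficient designs (monomorphic variants, or variants carried only
by exposed samples, making X_r and D.X_r collinear) are detected by a
scale-normalized condition-number check; their rows are retained with
missing p-values. Samples missing the phenotype are excluded globally;
samples missing a dosage are excluded per variant, with Sigma subset
and re-factored for those variants (complete case, no imputation — in
contrast to the GRM, where missing dosages are mean-imputed per variant
as GCTA does). The tested variant remains in K by design: with the
marker included twice the null inflation factor is exactly 1 when the
model is correct, which makes miscalibration visible;
leave-one-chromosome-out kinship is deliberately out of scope.

The genomic-control inflation factor is
lambda_GC = median(chi^2-equivalents of the p-values) / 0.4549364...,
computed separately for SNP and GxE p-value families; missing p-values
are excluded. QQ data are emitted as expected-vs-observed -log10 p
tables with ties broken by variant ID for determinism.

## Synthetic study generator

The simulator emulates a structured GxE GWAS of two diverged
populations under the global null (no causal variant), so lambda_GC
measures miscalibration only. Genotypes follow the Balding–Nichols
model: ancestral frequency p ~ Uniform(maf_floor, 1 - maf_floor),
population frequencies Beta(p(1-F)/F, (1-p)(1-F)/F), dosages
Binomial(2, p_pop); variants whose realized minor-allele frequency
falls below the floor in either population are rejected and redrawn,
mimicking a common-variant chip panel. Exposure is assigned with exact
per-population counts — balanced (half exposed in each population) or
biased (an `exposure_ratio` fraction exposed in one population and its
complement in the other, the scenario where exposure correlates with
ancestry). Phenotypes are drawn from
N(0, sigma_g^2 K + sigma_d^2 K^D + sigma_e^2 I) using the realized K
and K^D of each replicate.

Default study conditions: 1,000 individuals per population, 10,000
variants with a 5% MAF floor, balanced exposure, variance fractions
(0.40, 0.20, 0.40), 20 replicates, and Fst = 0.004 — the order of
magnitude separating two nearby European populations, exposed as a
config knob since the exact divergence of any particular population
pair is not a property of the model. Each replicate draws a fresh
genotype panel for maximal independence. A full-scale run (~100k
variants, 100 replicates) is a config change, not a code change; the
defaults are sized for a desktop CPU.

What the generator deliberately does not emulate: linkage
disequilibrium (variants are independent given the population
frequencies), minor-allele-frequency spectra of real chips beyond the
floor, cryptic relatedness within populations, ascertainment, or
genotyping error. The calibration claims tested here rest on the
polygenic-null covariance structure, which depends on between-
population structure rather than on LD, so medians of lambda_GC are
comparable to real-haplotype simulations in character though not to
printed third digits.

For the experiment that varies the implanted GxE fraction over
{0, 0.05, 0.1, 0.15, 0.2} (holding sigma_g^2 : sigma_e^2 = 1), each
replicate shares its three Gaussian draws (one per covariance
component) across grid points and only rescales them — common random
numbers. The median-based lambda_GC estimator has Monte-Carlo noise
comparable to the grid spacing at desk scale, and CRN removes the
between-point component of that noise without changing any marginal
distribution, making the monotonicity of the lambda profile visible at
10 replicates of 2,000 variants. The two mixed models are additionally
fitted at the sigma_d^2 = 0 grid point, where all three methods should
(and do) agree.

## Quality control

Phenotype screens mirror common eQTL practice: drop phenotypes with
Shapiro–Wilk p < 0.05 (constant phenotypes are reported as
"degenerate", not errors), and drop phenotypes with five or more values
more than 2 SD from the mean, with mean and SD computed in a single
pass that includes the outliers themselves. Note the 2-SD rule is
aggressive by construction: a normal phenotype of n samples has
~0.046 n such values in expectation, so the count threshold should be
chosen relative to n (the default 5 corresponds to ~3% of 147 samples).
Variant filters: MAF >= 0.10, Hardy–Weinberg p >= 1e-4, missing
fraction <= 0.05, with one primary reason recorded per dropped variant
(priority maf > hwe > missing). The HWE test defaults to the 1-df
chi-square goodness-of-fit without continuity correction; an exact
(Wigginton-style) test is available behind a flag since no test is
canonical at these thresholds. Rank-based inverse-normal
(quantile) normalization maps values to Phi^-1((rank - 0.5)/n) with
ties averaged, either over the whole sample or within exposure groups;
the (rank - 0.5)/n offset is symmetric and avoids infinite quantiles,
and the transform is idempotent.

## Numerical choices and edge cases

* Kinship matrices are symmetrized on construction (tolerance 1e-8) and
  genetic-role matrices can be PSD-checked (smallest eigenvalue >=
  -1e-8 x largest); K^D is *not* forced PSD — masking can break
  semidefiniteness — because only Sigma needs to be positive definite,
  which is verified where it is factored. For binary exposures K^D is
  automatically PSD (it is block-diagonal in principal submatrices of
  K).
* The phenotype simulator floors Sigma eigenvalues at 1e-10 x max if a
  Cholesky fails; an indefinite Sigma after flooring raises.
* p-values are clamped to the smallest positive float so they lie in
  (0, 1].
* All randomness flows through numpy Generators; replicate streams are
  spawned from a single SeedSequence so experiments are reproducible
  end-to-end and replicates are independent.
* Scan output restores the input variant order regardless of internal
  batching; permuting input variants permutes output rows only.

## Scale of the shipped experiments

The package's own test-suite and acceptance experiments run the study
at 20 replicates x 2,000 individuals x 10,000 variants (the full
published design used ~99.6k chip variants and 100 replicates of 1000
Genomes haplotypes; the scaled panel keeps the sample size and
structure and reduces the variant count and replicate count to desktop
runtimes). The sigma_d^2 grid runs at 2,000 variants and 10 replicates
with CRN as described above. Quantities that depend mainly on n and
the structure (lambda medians, variance fractions) are stable under
this scaling; extreme-tail quantities (the maximum lambda over 100
replicates) are not re-creatable from 20 replicates and are treated as
upper bounds.

## Known limitations

* No LD-aware or haplotype-based simulation; no case-control
  ascertainment or selection scenarios.
* Binary-trait (logistic) models, score/likelihood-ratio alternatives,
  case-only GEI designs, multiple simultaneous environments, bivariate
  REML and BLUP prediction are out of scope.
* The two-kinship REML path is O(n^3) per iteration; it is practical to
  a few thousand samples on one core, beyond which a low-rank or
  conjugate-gradient strategy would be needed.
* With n in the low hundreds, K and K^D overlap so strongly that
  individual variance-component estimates are very noisy (boundary
  estimates are common and flagged); means over replicates are the
  meaningful quantity at that scale.
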