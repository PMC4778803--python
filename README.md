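# gxelmm

Linear mixed models with **two random effects** for gene-by-environment
interaction (GxE) GWAS under population structure.

## The problem

In a structured sample (multiple populations, cryptic relatedness), the
residual of a single-variant regression contains every *other* variant's
effect, so related individuals have correlated residuals and SNP test
statistics inflate — the classic motivation for mixed-model GWAS. The
same argument applies to interaction effects: individuals who are
genetically related **and share an environmental exposure** also share
the polygenic-by-environment part of the residual. A mixed model with
the genetic kinship alone corrects SNP statistics but leaves GxE
statistics inflated; uncorrected regression inflates both.

`gxelmm` tests, per variant r,

    y = mu + beta_r X_r + delta D + gamma_r (D . X_r) + u + v + e

with var(**u**) = sigma_g^2 **K**, var(**v**) = sigma_d^2 **K**^D,
var(**e**) = sigma_e^2 **I**, where **K** is the standardized-genotype
relationship matrix and **K**^D is **K** restricted to pairs sharing an
environment (K^D_ij = K_ij if D_i = D_j, else 0; continuous exposures
use a similarity kernel instead of the indicator). Variance components
are estimated once per phenotype by AI-REML and reused for every
variant (EMMAX strategy); coefficients come from GLS,
(X' Sigma^-1 X)^-1 X' Sigma^-1 y, each tested with a 1-df F statistic.
Calibration is judged by the genomic-control inflation factor
lambda_GC = median(chi^2 equivalents of p) / 0.4549.

Who it is for: anyone running GWAS-style interaction scans — human
cohorts with environmental exposures, expression-by-treatment eQTL
panels, or model-organism panels with strong relatedness — who needs
GxE p-values that stay calibrated under structure.

## What is in the box

* `io` — PLINK .bed/.bim/.fam and dosage-TSV genotypes, GCTA GRM
  dialects and square-TSV kinships, phenotype/exposure files, results
  tables. All joins are by sample ID, never row order.
* `kinship` — GRM construction; binary-mask and continuous-kernel GxE
  kinships (range-scaled and normal-CDF kernels).
* `varcomp` — AI-REML for one or two relatedness matrices plus noise,
  with standard errors, variance fractions and delta-method fraction
  SEs.
* `assoc` — OLS / one-RE / two-RE / PCs-x-environment scans, single-
  variant tests, lambda_GC and QQ diagnostics.
* `popsim` — Balding–Nichols two-population null-study generator
  (structured genotypes, exposure schemes, MVN phenotypes) and the
  replicate experiment driver.
* `preprocess` — Shapiro–Wilk and outlier phenotype screens,
  MAF/HWE/missingness variant QC, (grouped) quantile normalization.
* `cli` — `gxelmm simulate | qc | kinship | reml | scan | qq | bench`,
  a thin shell over the library with per-run JSON manifests.
* `examples/` — four short narrative scripts, one per capability.

## Worked example

`examples/01_simulate_and_scan.py` simulates a two-population null study
(no causal variant, genetic and GxE kinships explaining 40% and 20% of
phenotypic variance) and scans it twice:

```text
$ python examples/01_simulate_and_scan.py
simulated 1000 individuals x 4000 variants (two populations, Fst 0.05)
OLS    : lambda_GC(SNP) = 1.022, lambda_GC(GxE) = 1.573
two-RE : lambda_GC(SNP) = 1.003, lambda_GC(GxE) = 1.034
```

Read: under the null every calibrated test should have lambda_GC near
1. In this draw plain OLS mistakes shared ancestry for interaction
signal (lambda_GC(GxE) = 1.57 — more than half of the apparent median
association signal is spurious); weighting the same scan by the fitted
covariance sigma_g^2 K + sigma_d^2 K^D + sigma_e^2 I brings it back to
~1. `examples/02_variance_components.py` shows the REML recovery of
the implanted variance fractions, and why a one-random-effect fit
overestimates heritability when a GxE component exists.

The same pipeline from the shell:

```bash
gxelmm simulate --out study --n-per-pop 500 --m-variants 4000 --fst 0.05 --seed 2024
gxelmm kinship  --geno study.geno.tsv --out study --gxe --exposure study.exposure.tsv
gxelmm reml     --grm study.kinship.tsv --gxe-grm study.gxe_kinship.tsv \
                --pheno study.pheno.tsv --exposure study.exposure.tsv --out study.hsq
gxelmm scan     --geno study.geno.tsv --mode 2re --grm study.kinship.tsv \
                --gxe-grm study.gxe_kinship.tsv --pheno study.pheno.tsv \
                --exposure study.exposure.tsv --out study.assoc.tsv --qq-out study.qq.tsv
```

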