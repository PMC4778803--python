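"""Population structure inflates GxE statistics; two random effects fix it.

Simulates a small two-population null study (no causal variant), scans
it with the uncorrected OLS interaction model and with the
two-random-effect mixed model, and prints the genomic-control inflation
factor lambda_GC for both the SNP and the GxE statistic families.
Under the null, a calibrated test has lambda_GC near 1; values above 1
mean the model mistakes shared ancestry for association signal.

The divergence here (Fst = 0.05) is exaggerated relative to the
package's default study conditions so the effect is visible at a size
that runs in seconds.
"""

from gxelmm import (
    ModelSpec,
    SimulationConfig,
    fit_reml,
    inflation_report,
    scan,
    simulate_dataset,
)

cfg = SimulationConfig(
    n_per_pop=500, m_variants=4000, fst=0.05, seed=2024
)
data = simulate_dataset(cfg)
G, y, D, K, KD = (
    data["genotypes"],
    data["phenotype"],
    data["exposure"],
    data["K"],
    data["KD"],
)
print(f"simulated {G.n_samples} individuals x {G.n_variants} variants "
      f"(two populations, Fst {cfg.fst})")

ols = inflation_report(scan(G, y, D, ModelSpec(mode="ols")))
print(f"OLS    : lambda_GC(SNP) = {ols.lambda_snp:.3f}, "
      f"lambda_GC(GxE) = {ols.lambda_gei:.3f}")

vc = fit_reml(y, [K, KD], exposure=D)
two = inflation_report(
    scan(G, y, D, ModelSpec(mode="two_re", vc=vc, kinships=[K, KD]))
)
print(f"two-RE : lambda_GC(SNP) = {two.lambda_snp:.3f}, "
      f"lambda_GC(GxE) = {two.lambda_gei:.3f}")

print(
    "\nGxE statistics are inflated under OLS because related individuals "
    "sharing an\nexposure also share residual polygenic-by-environment "
    "signal; weighting the scan\nby the fitted covariance "
    "sigma_g^2 K + sigma_d^2 K^D + sigma_e^2 I restores\ncalibration "
    "(any single draw is noisy; medians over replicates are the stable\n"
    "summary, see scripts/acceptance.py)."
)
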