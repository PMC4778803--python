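"""Estimating how much phenotypic variance the GxE kinship explains.

Simulates a phenotype in which the genetic kinship K explains 40% of
the variance and the GxE kinship K^D explains 20%, then recovers the
three components by AI-REML. The one-random-effect fit of the same data
is shown for contrast: with the GxE component unmodelled, the genetic
fraction absorbs part of it and is overestimated.
"""

from gxelmm import (
    SimulationConfig,
    fit_reml,
    simulate_dataset,
    variance_fractions,
)

cfg = SimulationConfig(n_per_pop=500, m_variants=5000, seed=7)
data = simulate_dataset(cfg)
y, D, K, KD = data["phenotype"], data["exposure"], data["K"], data["KD"]
print(f"truth: fractions (genetic, gxe, residual) = {cfg.fractions}")

vc2 = fit_reml(y, [K, KD], exposure=D)
print("\ntwo-random-effect REML fit "
      f"({vc2.n_iter} iterations, converged={vc2.converged}):")
print(variance_fractions(vc2).to_string(index=False, float_format="%.4f"))

vc1 = fit_reml(y, [K], exposure=D)
print("\none-random-effect fit of the same phenotype:")
print(variance_fractions(vc1).to_string(index=False, float_format="%.4f"))
print(
    "\nA single replicate is noisy (the two kinships overlap heavily), but "
    "the one-RE\ngenetic fraction sits above the implanted 0.40 because it "
    "absorbs the unmodelled\nGxE variance."
)
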