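"""Building a GxE kinship for a continuous environmental exposure.

For a binary exposure the GxE kinship simply zeroes the relatedness of
pairs in different groups. For a continuous exposure (dosage of a drug,
dietary fat, age...) the relatedness is attenuated by a similarity
kernel f(D_i, D_j) in [0, 1]: the range-scaled kernel
1 - |D_i - D_j| / R, or the normal-CDF kernel that compares the
exposures' standard-normal quantiles (robust to the exposure's scale
and outliers). Which kernel is appropriate depends on the scale of the
exposure; both are shown.
"""

import numpy as np

from gxelmm import (
    ContinuousExposureKernel,
    ExposureVector,
    SimulationConfig,
    gxe_kinship_continuous,
    simulate_dataset,
)

cfg = SimulationConfig(n_per_pop=100, m_variants=1500, seed=5)
data = simulate_dataset(cfg)
K = data["K"]
rng = np.random.default_rng(5)
D = ExposureVector(K.samples, rng.gamma(3.0, 2.0, K.n_samples), mode="continuous")
print(f"continuous exposure: range {D.range:.2f}, "
      f"mean {D.values.mean():.2f}, sd {D.values.std():.2f}")

for kernel, label in (
    (ContinuousExposureKernel.range_scaled(), "range-scaled"),
    (ContinuousExposureKernel.normal_cdf(), "normal-CDF"),
):
    KD = gxe_kinship_continuous(K, D, kernel)
    off = ~np.eye(K.n_samples, dtype=bool)
    shrink = np.abs(KD.values[off]).sum() / np.abs(K.values[off]).sum()
    print(f"{label:13s}: off-diagonal |K^D| / |K| = {shrink:.3f} "
          f"(diagonal preserved: {np.allclose(np.diag(KD.values), np.diag(K.values))})")

print(
    "\nBoth kernels leave each individual's self-relatedness intact and "
    "shrink pair\nrelatedness toward zero as exposures diverge; the "
    "normal-CDF kernel shrinks less\nfor pairs in the bulk of the exposure "
    "distribution and more in the tails."
)
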