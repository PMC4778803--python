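"""Synthetic structured GxE GWAS studies.

Generates the two-population null experiment used throughout the test
suite and the acceptance analysis: Balding–Nichols genotypes for two
populations diverged by Fst, a dichotomous exposure assigned within
populations (balanced or deliberately imbalanced between them), and
phenotypes drawn from the multivariate normal polygenic-plus-GxE model

    y ~ N(0, sigma_g^2 K + sigma_d^2 K^D + sigma_e^2 I)

with no causal variant, so both SNP and GxE statistic families are null
and their genomic-control inflation factors measure miscalibration only.

Under the Balding–Nichols model the ancestral allele frequency is drawn
uniformly, each population's frequency from a Beta distribution around
it parameterized by Fst, and dosages are Binomial(2, p_pop); variants
whose realized minor allele frequency falls below the floor in either
population are rejected and redrawn. No linkage disequilibrium is
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assoc import ModelSpec, inflation_report, scan
from .kinship import compute_grm, gxe_kinship_binary
from .types import ExposureVector, GenotypeMatrix, KinshipMatrix, PhenotypeVector
from .varcomp import fit_reml

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_genotypes",
    "assign_exposure",
    "simulate_phenotype",
    "simulate_dataset",
    "run_replicates",
    "run_sigma_grid",
]


@dataclass
class SimulationConfig:
    """Parameters of the two-population null GxE study.

    Defaults are the desk-scale study conditions: 1,000 individuals per
    population, 10,000 chip-like variants with MAF > 5% in both
    populations, Fst 0.004 (two closely related European-scale
    populations), balanced exposure, and variance fractions
    (0.4, 0.2, 0.4) for genetic, GxE and residual components.
    """

    n_per_pop: int = 1000
    m_variants: int = 10_000
    fst: float = 0.004
    maf_floor: float = 0.05
    exposure_scheme: str = "balanced"  # "balanced" | "biased"
    exposure_ratio: float = 0.6  # exposed fraction in pop 1 when biased
    sigma_g2: float = 0.4
    sigma_d2: float = 0.2
    sigma_e2: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_pop <= 0 or self.m_variants <= 0:
            raise ValueError("sample and variant counts must be positive")
        if not 0 < self.fst < 0.5:
            raise ValueError(f"fst must be in (0, 0.5), got {self.fst}")
        if not 0 <= self.maf_floor < 0.5:
            raise ValueError(f"maf_floor must be in [0, 0.5), got {self.maf_floor}")
        if self.exposure_scheme not in ("balanced", "biased"):
            raise ValueError("exposure_scheme must be balanced|biased")
        if self.exposure_scheme == "biased" and not 0.5 <= self.exposure_ratio < 1:
            raise ValueError(
                f"biased exposure ratio must be in [0.5, 1), got {self.exposure_ratio}"
            )
        total = self.sigma_g2 + self.sigma_d2 + self.sigma_e2
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"variance fractions must sum to 1, got {total}")

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.sigma_g2, self.sigma_d2, self.sigma_e2)


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset, for recovery experiments."""

    pop_labels: np.ndarray
    exposure: np.ndarray | None
    fractions: tuple[float, float, float]
    seed: int


def _rng(cfg: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Balding–Nichols genotypes for two populations of ``n_per_pop``.

    Deterministic under ``cfg.seed`` (or the supplied generator);
    variants failing the per-population realized-MAF floor are redrawn.
    """
    rng = _rng(cfg, rng)
    n, m, F = cfg.n_per_pop, cfg.m_variants, cfg.fst
    a = (1.0 - F) / F
    lo = max(cfg.maf_floor, 1e-6)
    blocks: list[np.ndarray] = []
    got = 0
    while got < m:
        batch = max(256, int(1.4 * (m - got)))
        p_anc = rng.uniform(lo, 1.0 - lo, size=batch)
        p_pop = rng.beta(p_anc * a, (1.0 - p_anc) * a, size=(2, batch))
        p_pop = np.clip(p_pop, 1e-12, 1.0 - 1e-12)
        dos = np.empty((2 * n, batch), dtype=np.int8)
        dos[:n] = rng.binomial(2, p_pop[0], size=(n, batch))
        dos[n:] = rng.binomial(2, p_pop[1], size=(n, batch))
        phat = np.stack([dos[:n].mean(axis=0), dos[n:].mean(axis=0)]) / 2.0
        maf = np.minimum(phat, 1.0 - phat).min(axis=0)
        ok = maf >= cfg.maf_floor
        blocks.append(dos[:, ok][:, : m - got])
        got += min(int(ok.sum()), m - got)
    dosages = np.concatenate(blocks, axis=1).astype(float)
    samples = [f"P1_{i:05d}" for i in range(n)] + [f"P2_{i:05d}" for i in range(n)]
    ids = [f"snp{j:06d}" for j in range(m)]
    variants = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, m + 1) * 1000, "a1": "A", "a2": "B"},
        index=pd.Index(ids, name="id"),
    )
    G = GenotypeMatrix(samples, variants, dosages, validate=False)
    truth = TruthRecord(
        pop_labels=np.repeat([0, 1], n),
        exposure=None,
        fractions=cfg.fractions,
        seed=cfg.seed,
    )
    return G, truth


def assign_exposure(
    cfg: SimulationConfig,
    pop_labels: np.ndarray,
    samples: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> ExposureVector:
    """Dichotomous exposure with exact per-population counts.

    Balanced: each population has exactly half exposed. Biased: the
    exposed fraction is ``exposure_ratio`` in population 1 and
    ``1 - exposure_ratio`` in population 2 (counts rounded toward the
    stated ratio). Assignment within a population is random under seed.
    """
    rng = _rng(cfg, rng)
    pop_labels = np.asarray(pop_labels)
    n_total = len(pop_labels)
    if samples is None:
        samples = [f"S{i:05d}" for i in range(n_total)]
    values = np.zeros(n_total)
    for pop in np.unique(pop_labels):
        idx = np.nonzero(pop_labels == pop)[0]
        if cfg.exposure_scheme == "balanced":
            n_exposed = len(idx) // 2
        else:
            ratio = cfg.exposure_ratio if pop == np.unique(pop_labels)[0] else 1 - cfg.exposure_ratio
            n_exposed = int(round(ratio * len(idx)))
        chosen = rng.permutation(idx)[:n_exposed]
        values[chosen] = 1.0
    return ExposureVector(list(samples), values, mode="binary")


def simulate_phenotype(
    K: KinshipMatrix,
    KD: KinshipMatrix | None,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PhenotypeVector:
    """One draw of y ~ N(0, sigma_g2 K + sigma_d2 K^D + sigma_e2 I).

    The covariance is Cholesky-factored; if it is numerically indefinite
    its eigenvalues are floored at a tiny positive value (a warning-level
    event surfaced as an exception only if flooring fails).
    """
    rng = _rng(cfg, rng)
    n = K.n_samples
    Sigma = cfg.sigma_g2 * K.values + cfg.sigma_e2 * np.eye(n)
    if KD is not None:
        if KD.samples != K.samples:
            KD = KD.reindex(K.samples)
        Sigma = Sigma + cfg.sigma_d2 * KD.values
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(Sigma)
        floor = 1e-10 * max(w.max(), 1.0)
        if w.max() <= 0:
            raise np.linalg.LinAlgError(
                "phenotype covariance not positive definite even after flooring"
            )
        L = U * np.sqrt(np.maximum(w, floor))
    y = L @ rng.standard_normal(n)
    return PhenotypeVector(list(K.samples), y)


def simulate_dataset(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dict:
    """Full study draw: genotypes, exposure, K, K^D, phenotype, truth."""
    rng = _rng(cfg, rng)
    G, truth = simulate_genotypes(cfg, rng)
    D = assign_exposure(cfg, truth.pop_labels, samples=G.samples, rng=rng)
    K = compute_grm(G)
    KD = gxe_kinship_binary(K, D)
    y = simulate_phenotype(K, KD, cfg, rng)
    truth.exposure = D.values.copy()
    return {"genotypes": G, "exposure": D, "K": K, "KD": KD, "phenotype": y, "truth": truth}


def _fit_and_scan(data, mode):
    """One model's lambda_GC pair (and REML fractions where applicable)."""
    G, y, D, K, KD = (
        data["genotypes"],
        data["phenotype"],
        data["exposure"],
        data["K"],
        data["KD"],
    )
    frac = dict(frac_g=np.nan, frac_d=np.nan, frac_e=np.nan)
    if mode == "ols":
        spec = ModelSpec(mode="ols")
    elif mode == "pc_x_env":
        spec = ModelSpec(mode="pc_x_env", kinships=[K], n_pcs=10)
    elif mode == "one_re":
        vc = fit_reml(y, [K], exposure=D)
        f = vc.fractions
        frac = dict(frac_g=f[0], frac_d=np.nan, frac_e=f[1])
        spec = ModelSpec(mode="one_re", vc=vc, kinships=[K])
    elif mode == "two_re":
        vc = fit_reml(y, [K, KD], exposure=D)
        f = vc.fractions
        frac = dict(frac_g=f[0], frac_d=f[1], frac_e=f[2])
        spec = ModelSpec(mode="two_re", vc=vc, kinships=[K, KD])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rep = inflation_report(scan(G, y, D, spec))
    return dict(lambda_snp=rep.lambda_snp, lambda_gei=rep.lambda_gei, **frac)


def run_replicates(
    cfg: SimulationConfig,
    n_replicates: int,
    modes: tuple[str, ...] = ("ols", "one_re", "two_re"),
) -> pd.DataFrame:
    """End-to-end null experiment: per-replicate lambda_GC by model.

    Each replicate draws a fresh genotype panel, exposure and phenotype
    from per-replicate substreams of ``cfg.seed``. Returns one row per
    (replicate, mode) with lambda_GC for SNP and GxE families and, for
    the mixed models, the REML variance fractions.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(n_replicates)
    rows = []
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        data = simulate_dataset(cfg, rng)
        for mode in modes:
            rows.append(dict(replicate=r, mode=mode, **_fit_and_scan(data, mode)))
    return pd.DataFrame(rows)


def run_sigma_grid(
    cfg: SimulationConfig,
    sigma_d_grid: tuple[float, ...] = (0.0, 0.05, 0.1, 0.15, 0.2),
    n_replicates: int = 10,
    modes_at_zero: tuple[str, ...] = (),
) -> pd.DataFrame:
    """lambda_GC across a grid of GxE variance fractions (OLS scans).

    The genetic:residual ratio is held at the ratio implied by ``cfg``
    while sigma_d^2 varies. Within a replicate the three Gaussian draws
    (genetic, GxE, residual) are shared across grid points and only
    rescaled — common random numbers — so the grid's lambda profile is
    not swamped by Monte-Carlo noise in the median-based estimator.
    ``modes_at_zero`` optionally adds mixed-model scans at the
    sigma_d^2 = 0 grid point for method comparison.
    """
    ratio_g = cfg.sigma_g2 / (cfg.sigma_g2 + cfg.sigma_e2)
    streams = np.random.SeedSequence(cfg.seed).spawn(n_replicates)
    rows = []
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        G, truth = simulate_genotypes(cfg, rng)
        D = assign_exposure(cfg, truth.pop_labels, samples=G.samples, rng=rng)
        K = compute_grm(G)
        KD = gxe_kinship_binary(K, D)
        n = K.n_samples
        Lg = _chol_psd(K.values)
        Ld = _chol_psd(KD.values)
        zg = Lg @ rng.standard_normal(n)
        zd = Ld @ rng.standard_normal(n)
        ze = rng.standard_normal(n)
        for sd2 in sigma_d_grid:
            sg2 = ratio_g * (1.0 - sd2)
            se2 = 1.0 - sd2 - sg2
            y = PhenotypeVector(
                list(K.samples),
                np.sqrt(sg2) * zg + np.sqrt(sd2) * zd + np.sqrt(se2) * ze,
            )
            data = {"genotypes": G, "phenotype": y, "exposure": D, "K": K, "KD": KD}
            rows.append(
                dict(replicate=r, sigma_d2=sd2, mode="ols", **_fit_and_scan(data, "ols"))
            )
            if sd2 == 0.0:
                for mode in modes_at_zero:
                    rows.append(
                        dict(
                            replicate=r,
                            sigma_d2=sd2,
                            mode=mode,
                            **_fit_and_scan(data, mode),
                        )
                    )
    return pd.DataFrame(rows)


def _chol_psd(A: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a PSD matrix (eigen fallback for semidefinite)."""
    try:
        return np.linalg.cholesky(A + 1e-12 * np.eye(len(A)))
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(A)
        return U * np.sqrt(np.maximum(w, 0.0))
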