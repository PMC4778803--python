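"""Genetic and GxE kinship construction.

The genetic relationship matrix (GRM) between individuals i and j is the
average over variants of standardized-genotype products,

    K_ij = (1/m) * sum_s (x_is - 2 p_s)(x_js - 2 p_s) / (2 p_s (1 - p_s)),

with p_s the sample allele frequency of variant s. The GxE kinship K^D
restricts relatedness to pairs sharing an environment: for a binary
exposure D, K^D_ij = K_ij when D_i = D_j and 0 otherwise; for a
continuous exposure, K^D_ij = K_ij * f(D_i, D_j) for a similarity kernel
f with f(d, d) = 1 and values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm

from .types import ExposureVector, GenotypeMatrix, KinshipMatrix, aligned

__all__ = [
    "compute_grm",
    "gxe_kinship_binary",
    "gxe_kinship_continuous",
    "ContinuousExposureKernel",
]


def compute_grm(G: GenotypeMatrix, maf_floor: float = 0.0) -> KinshipMatrix:
    """Standardized-genotype GRM with missing dosages mean-imputed.

    Monomorphic variants (p in {0, 1}) and variants with minor allele
    frequency below ``maf_floor`` are excluded from the average; the 1/m
    prefactor counts retained variants only. Missing dosages are set to
    2 p_s before standardization, i.e. they contribute zero.
    """
    X = np.array(G.dosages, dtype=float)
    p = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = (p > 0.0) & (p < 1.0) & (maf >= maf_floor)
    if not keep.any():
        raise ValueError(
            "no polymorphic variant survives the allele-frequency check; "
            "cannot estimate a GRM"
        )
    X = X[:, keep]
    p = p[keep]
    nan = np.isnan(X)
    if nan.any():
        X[nan] = (2.0 * p)[np.nonzero(nan)[1]]
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = Z.shape[1]
    K = (Z @ Z.T) / m
    return KinshipMatrix(G.samples, K, role="genetic")


def gxe_kinship_binary(K: KinshipMatrix, D: ExposureVector) -> KinshipMatrix:
    """K^D for a binary exposure: K masked to same-exposure pairs.

    The diagonal is preserved (every sample shares its own exposure) and
    the construction is invariant to flipping all exposure labels.
    """
    if D.mode != "binary":
        raise ValueError(
            "exposure is not binary; use gxe_kinship_continuous with a "
            "similarity kernel instead"
        )
    K, D = aligned(K, D)
    same = D.values[:, None] == D.values[None, :]
    return KinshipMatrix(K.samples, np.where(same, K.values, 0.0), role="gxe")


@dataclass
class ContinuousExposureKernel:
    """Similarity kernel f(D_i, D_j) in [0, 1] for continuous exposures.

    Two built-in forms: ``range-scaled`` uses f = 1 - |D_i - D_j| / R with
    R the exposure range, and ``normal-cdf`` uses
    f = 1 - |Phi((D_i - mu)/sigma) - Phi((D_j - mu)/sigma)|. Unset
    parameters are taken from the exposure itself. A ``custom`` kernel
    wraps any callable f(d_i, d_j) (array-broadcastable).
    """

    kind: str
    R: float | None = None
    mu: float | None = None
    sigma: float | None = None
    func: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    @classmethod
    def range_scaled(cls, R: float | None = None) -> "ContinuousExposureKernel":
        return cls(kind="range-scaled", R=R)

    @classmethod
    def normal_cdf(
        cls, mu: float | None = None, sigma: float | None = None
    ) -> "ContinuousExposureKernel":
        return cls(kind="normal-cdf", mu=mu, sigma=sigma)

    @classmethod
    def custom(cls, func: Callable) -> "ContinuousExposureKernel":
        return cls(kind="custom", func=func)

    def factor_matrix(self, d: np.ndarray) -> np.ndarray:
        """Pairwise factor matrix f(D_i, D_j) for exposure values ``d``."""
        d = np.asarray(d, dtype=float)
        if self.kind == "range-scaled":
            R = self.R if self.R is not None else float(np.ptp(d))
            if R <= 0:
                raise ValueError(
                    "exposure range is zero; the range-scaled kernel is "
                    "degenerate for a constant exposure"
                )
            f = 1.0 - np.abs(d[:, None] - d[None, :]) / R
        elif self.kind == "normal-cdf":
            mu = self.mu if self.mu is not None else float(np.mean(d))
            sigma = self.sigma if self.sigma is not None else float(np.std(d))
            if sigma <= 0:
                raise ValueError("sigma must be positive for the normal-cdf kernel")
            u = norm.cdf((d - mu) / sigma)
            f = 1.0 - np.abs(u[:, None] - u[None, :])
        elif self.kind == "custom":
            if self.func is None:
                raise ValueError("custom kernel requires a callable")
            f = np.asarray(self.func(d[:, None], d[None, :]), dtype=float)
        else:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if f.min() < -1e-12 or f.max() > 1 + 1e-12:
            raise ValueError("kernel factors must lie in [0, 1]")
        return np.clip(f, 0.0, 1.0)


def gxe_kinship_continuous(
    K: KinshipMatrix, D: ExposureVector, kernel: ContinuousExposureKernel
) -> KinshipMatrix:
    """K^D_ij = K_ij * f(D_i, D_j) for a continuous exposure kernel.

    Entries never exceed those of K in absolute value; the diagonal of K
    is preserved since f(d, d) = 1.
    """
    K, D = aligned(K, D)
    f = kernel.factor_matrix(D.values)
    return KinshipMatrix(K.samples, K.values * f, role="gxe")
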