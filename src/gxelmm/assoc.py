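"""Per-variant SNP and GxE association tests under four models.

For each variant r the fixed-effect model is the interaction regression

    y = mu + beta_r X_r + delta D + gamma_r (D * X_r) [+ covariates] + eps

fitted by generalized least squares with covariance Sigma chosen by the
model mode:

* ``ols``     — Sigma = I (no structure correction);
* ``one_re``  — Sigma = sigma_g^2 K + sigma_e^2 I (corrects SNP statistics
  only);
* ``two_re``  — Sigma = sigma_g^2 K + sigma_d^2 K^D + sigma_e^2 I (corrects
  both SNP and GxE statistics);
* ``pc_x_env``— Sigma = I plus top kinship eigenvectors and their products
  with D as fixed covariates.

Variance components are estimated once per phenotype under the null and
reused for every variant (EMMAX strategy): Sigma is Cholesky-factored a
single time, phenotype and covariates are whitened by a triangular
solve, and variants are streamed through vectorized normal equations.
Each coefficient is tested with a 1-df F statistic (coef/SE)^2 against
F(1, n - p); a joint 2-df test of (beta_r, gamma_r) is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr as scipy_qr
from scipy.linalg import solve_triangular

from .types import (
    ExposureVector,
    GenotypeMatrix,
    KinshipMatrix,
    PhenotypeVector,
    aligned,
)
from .varcomp import VarianceComponents

__all__ = [
    "ModelSpec",
    "test_variant",
    "scan",
    "pc_env_covariates",
    "inflation_factor",
    "inflation_report",
    "InflationReport",
]

#: median of the chi-square distribution with 1 df
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))

_MODES = ("ols", "one_re", "two_re", "pc_x_env")

# smallest representable p-value: keeps p in (0, 1] as promised
_P_FLOOR = 5e-324

# relative condition-number threshold flagging a rank-deficient design
_COND_MAX = 1e10


@dataclass
class ModelSpec:
    """Which covariance and fixed covariates a scan should use.

    ``kinships`` supplies K (and K^D for ``two_re``); ``vc`` the REML
    estimates that weight them. ``n_pcs`` > 0 adds top eigenvectors of
    the PC source kinship and their products with the exposure
    (``pc_x_env`` mode); ``pc_source`` picks the matrix whose
    eigenvectors are used ("genetic" or "gxe").
    """

    mode: str = "ols"
    vc: VarianceComponents | None = None
    kinships: list[KinshipMatrix] = field(default_factory=list)
    n_pcs: int = 0
    pc_source: str = "genetic"
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode in ("one_re", "two_re"):
            need = 1 if self.mode == "one_re" else 2
            if self.vc is None or len(self.kinships) < need:
                raise ValueError(
                    f"{self.mode} requires fitted variance components and "
                    f"{need} kinship matrix(es)"
                )

    def _kin_by_role(self, role: str) -> KinshipMatrix:
        for K in self.kinships:
            if K.role == role:
                return K
        raise ValueError(f"no kinship with role {role!r} in ModelSpec")

    def sigma(self, samples: list[str]) -> np.ndarray | None:
        """Covariance matrix on the given sample order; None means identity."""
        if self.mode in ("ols", "pc_x_env"):
            return None
        n = len(samples)
        if self.mode == "one_re":
            K = self._kin_by_role("genetic").reindex(samples)
            return self.vc.component("genetic") * K.values + self.vc.component(
                "residual"
            ) * np.eye(n)
        K = self._kin_by_role("genetic").reindex(samples)
        KD = self._kin_by_role("gxe").reindex(samples)
        return (
            self.vc.component("genetic") * K.values
            + self.vc.component("gxe") * KD.values
            + self.vc.component("residual") * np.eye(n)
        )


@dataclass
class InflationReport:
    """Genomic-control summary of a scan: lambda per statistic family."""

    lambda_snp: float
    lambda_gei: float
    n_tests: int
    neglog10_p_snp: np.ndarray
    neglog10_p_gei: np.ndarray


def inflation_factor(pvalues: np.ndarray) -> float:
    """Genomic-control lambda: median chi2-equivalent over 0.4549...

    Missing p-values are excluded; an empty input is an error.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no valid p-values for the inflation factor")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def inflation_report(results: pd.DataFrame) -> InflationReport:
    """Lambda_GC for SNP and GxE families plus sorted -log10 p for QQ plots.

    Ties in the sort order are broken by variant ID for determinism.
    """
    df = results.sort_values(["p_snp", "variant"], kind="mergesort")
    nl_snp = -np.log10(np.maximum(df["p_snp"].to_numpy(float), _P_FLOOR))
    df = results.sort_values(["p_gei", "variant"], kind="mergesort")
    nl_gei = -np.log10(np.maximum(df["p_gei"].to_numpy(float), _P_FLOOR))
    return InflationReport(
        lambda_snp=inflation_factor(results["p_snp"].to_numpy(float)),
        lambda_gei=inflation_factor(results["p_gei"].to_numpy(float)),
        n_tests=int(len(results)),
        neglog10_p_snp=nl_snp[np.isfinite(nl_snp)],
        neglog10_p_gei=nl_gei[np.isfinite(nl_gei)],
    )


def pc_env_covariates(K: KinshipMatrix, D: ExposureVector, k: int) -> np.ndarray:
    """Top-k kinship eigenvectors and their elementwise products with D.

    Eigenvectors are sorted by descending eigenvalue with the sign fixed
    so each vector's largest-magnitude loading is positive. Columns that
    are linearly dependent on earlier ones (e.g. PC_j * D when D is
    constant) are dropped to keep the design full rank. ``k = 0`` returns
    an empty (n, 0) array.
    """
    n = K.n_samples
    if k < 0 or k >= n:
        raise ValueError(f"need 0 <= k < n = {n}, got k = {k}")
    if k == 0:
        return np.empty((n, 0))
    K, D = aligned(K, D)
    w, U = np.linalg.eigh(K.values)
    order = np.argsort(w)[::-1]
    U = U[:, order[:k]]
    sign = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    sign[sign == 0] = 1.0
    U = U * sign
    cols = np.column_stack([U, U * D.values[:, None]])
    # rank-revealing QR against the implicit intercept + D base design
    base = np.column_stack([np.ones(len(D.values)), D.values])
    full = np.column_stack([base, cols])
    _, R, piv = scipy_qr(full, mode="economic", pivoting=True)
    tol = np.abs(R[0, 0]) * max(full.shape) * np.finfo(float).eps
    rank_cols = {p for p, r in zip(piv, np.abs(np.diag(R))) if r > tol}
    keep = [j for j in range(cols.shape[1]) if (j + base.shape[1]) in rank_cols]
    return cols[:, keep]


def _prepare(y, D, spec, samples):
    """Whitening transform and base design on a fixed sample order."""
    Sigma = spec.sigma(samples)
    n = len(samples)
    cols = [np.ones(n), D.values]
    if spec.mode == "pc_x_env" and spec.n_pcs > 0:
        K = spec._kin_by_role(spec.pc_source if spec.pc_source in ("genetic", "gxe") else "genetic")
        cols.append(pc_env_covariates(K.reindex(samples), D, spec.n_pcs))
    if spec.covariates is not None:
        C = np.atleast_2d(np.asarray(spec.covariates, float))
        if C.shape[0] != n:
            C = C.T
        cols.append(C)
    X0 = np.column_stack([np.asarray(c).reshape(n, -1) for c in cols])
    if Sigma is None:
        L = None
        yw, X0w = y.values.copy(), X0
    else:
        L = np.linalg.cholesky(Sigma)
        yw = solve_triangular(L, y.values, lower=True, check_finite=False)
        X0w = solve_triangular(L, X0, lower=True, check_finite=False)
    return L, yw, X0w, X0.shape[1]


def _batched_gls(yw, X0w, Xw, DXw, variant_ids):
    """Vectorized per-variant interaction fits on whitened data.

    ``Xw``/``DXw`` are (n, m) whitened dosage and dosage-by-exposure
    columns. Returns a DataFrame of estimates and F-test p-values.
    """
    n, m = Xw.shape
    p0 = X0w.shape[1]
    p = p0 + 2
    B = X0w
    BtB = B.T @ B
    Bty = B.T @ yw
    BtX = B.T @ Xw      # (p0, m)
    BtDX = B.T @ DXw
    xx = np.einsum("ij,ij->j", Xw, Xw)
    xdx = np.einsum("ij,ij->j", Xw, DXw)
    dxdx = np.einsum("ij,ij->j", DXw, DXw)
    xy = Xw.T @ yw
    dxy = DXw.T @ yw
    yy = yw @ yw

    XtX = np.empty((m, p, p))
    XtX[:, :p0, :p0] = BtB
    XtX[:, :p0, p0] = BtX.T
    XtX[:, :p0, p0 + 1] = BtDX.T
    XtX[:, p0, :p0] = BtX.T
    XtX[:, p0 + 1, :p0] = BtDX.T
    XtX[:, p0, p0] = xx
    XtX[:, p0, p0 + 1] = xdx
    XtX[:, p0 + 1, p0] = xdx
    XtX[:, p0 + 1, p0 + 1] = dxdx
    Xty = np.empty((m, p))
    Xty[:, :p0] = Bty
    Xty[:, p0] = xy
    Xty[:, p0 + 1] = dxy

    # scale-normalized condition check flags rank-deficient designs
    # (monomorphic variants, interactions collinear with the dosage, ...)
    d = np.sqrt(np.maximum(np.einsum("mii->mi", XtX), np.finfo(float).tiny))
    XtX_n = XtX / d[:, :, None] / d[:, None, :]
    ok = np.linalg.cond(XtX_n) < _COND_MAX

    beta = np.full((m, p), np.nan)
    XtX_inv = np.full((m, p, p), np.nan)
    if ok.any():
        XtX_inv[ok] = np.linalg.inv(XtX[ok])
        beta[ok] = np.einsum("mij,mj->mi", XtX_inv[ok], Xty[ok])
    rss = yy - np.einsum("mi,mi->m", beta, Xty)
    df = n - p
    sigma2 = rss / df
    var_diag = np.einsum("mii->mi", XtX_inv) * sigma2[:, None]
    se = np.sqrt(np.maximum(var_diag, 0.0))

    def f_test(j):
        F = (beta[:, j] / se[:, j]) ** 2
        pv = stats.f.sf(F, 1, df)
        return np.maximum(pv, _P_FLOOR)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_snp = f_test(p0)
        p_gei = f_test(p0 + 1)
        # joint 2-df test of (beta_r, gamma_r)
        sub = XtX_inv[:, p0:, p0:]
        b2 = beta[:, p0:]
        det = sub[:, 0, 0] * sub[:, 1, 1] - sub[:, 0, 1] ** 2
        inv00 = sub[:, 1, 1] / det
        inv11 = sub[:, 0, 0] / det
        inv01 = -sub[:, 0, 1] / det
        quad = (
            b2[:, 0] ** 2 * inv00
            + 2 * b2[:, 0] * b2[:, 1] * inv01
            + b2[:, 1] ** 2 * inv11
        )
        F_joint = quad / 2.0 / sigma2
        p_joint = np.maximum(stats.f.sf(F_joint, 2, df), _P_FLOOR)

    out = pd.DataFrame(
        {
            "variant": variant_ids,
            "beta_snp": beta[:, p0],
            "se_snp": se[:, p0],
            "p_snp": p_snp,
            "gamma_gei": beta[:, p0 + 1],
            "se_gei": se[:, p0 + 1],
            "p_gei": p_gei,
            "delta_env": beta[:, 1],
            "p_joint": p_joint,
            "df_resid": df,
        }
    )
    bad = ~ok
    if bad.any():
        for c in ("beta_snp", "se_snp", "p_snp", "gamma_gei", "se_gei", "p_gei", "p_joint"):
            out.loc[bad, c] = np.nan
    return out


def scan(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    D: ExposureVector,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Stream all variants through the GLS interaction test.

    Samples are joined on ID across all inputs; samples with a missing
    phenotype are excluded globally, and samples with a missing dosage
    are excluded per variant (complete-case, with Sigma subset and
    re-factored for those variants). Results are identical to calling
    :func:`test_variant` per variant.
    """
    G, y, D = aligned(G, y, D)
    keep = np.isfinite(y.values)
    if not keep.all():
        ids = [s for s, k in zip(y.samples, keep) if k]
        G, y, D = G.reindex(ids), y.reindex(ids), D.reindex(ids)
    samples = y.samples
    L, yw, X0w, p0 = _prepare(y, D, spec, samples)

    dos = G.dosages
    complete = ~np.isnan(dos).any(axis=0)
    X = dos[:, complete]
    if L is None:
        Xw, DXw = X, X * D.values[:, None]
    else:
        Xw = solve_triangular(L, X, lower=True, check_finite=False)
        DXw = solve_triangular(
            L, X * D.values[:, None], lower=True, check_finite=False
        )
    ids_arr = np.asarray(G.variants.index, dtype=object)
    out = _batched_gls(yw, X0w, Xw, DXw, ids_arr[complete])

    if not complete.all():
        rows = []
        for j in np.nonzero(~complete)[0]:
            rows.append(
                _single_variant(
                    y, dos[:, j], D, spec, str(ids_arr[j])
                )
            )
        out = pd.concat([out, pd.DataFrame(rows)], ignore_index=True)
    # restore input variant order
    order = pd.Index(out["variant"]).get_indexer(ids_arr)
    out = out.iloc[order].reset_index(drop=True)
    out.insert(1, "chrom", G.variants["chrom"].to_numpy())
    out.insert(2, "pos", G.variants["pos"].to_numpy())
    out["model"] = spec.mode
    return out


def _single_variant(y, x, D, spec, variant_id):
    """Complete-case fit of one variant (used for missing dosages)."""
    ok = np.isfinite(x)
    ids = [s for s, k in zip(y.samples, ok) if k]
    ys, Ds = y.reindex(ids), D.reindex(ids)
    Lc, yw, X0w, p0 = _prepare(ys, Ds, spec, ids)
    xs = x[ok]
    if Lc is None:
        xw = xs[:, None]
        dxw = (xs * Ds.values)[:, None]
    else:
        xw = solve_triangular(Lc, xs[:, None], lower=True, check_finite=False)
        dxw = solve_triangular(
            Lc, (xs * Ds.values)[:, None], lower=True, check_finite=False
        )
    row = _batched_gls(yw, X0w, xw, dxw, np.array([variant_id], dtype=object)).iloc[0]
    return row.to_dict()


def test_variant(
    y: PhenotypeVector,
    x_r: np.ndarray,
    D: ExposureVector,
    spec: ModelSpec,
    variant_id: str = "variant",
) -> pd.Series:
    """GLS interaction test of a single variant dosage column.

    ``x_r`` must be aligned to ``y.samples``. Returns a Series with the
    SNP effect, GxE effect, exposure effect, F-test p-values and model
    tag; on a rank-deficient design the p-values are missing but the row
    is returned.
    """
    y2, D2 = aligned(y, D)
    x = np.asarray(x_r, float).ravel()
    if len(x) != len(y.samples):
        raise ValueError("dosage column length != number of samples")
    pos = {s: i for i, s in enumerate(y.samples)}
    x = x[[pos[s] for s in y2.samples]]
    keep = np.isfinite(y2.values)
    if not keep.all():
        ids = [s for s, k in zip(y2.samples, keep) if k]
        y2, D2, x = y2.reindex(ids), D2.reindex(ids), x[keep]
    row = _single_variant(y2, x, D2, spec, variant_id)
    row["model"] = spec.mode
    return pd.Series(row)
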