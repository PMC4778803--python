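"""GLS interaction tests, PC x environment covariates, lambda_GC."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from gxelmm import (
    ExposureVector,
    KinshipMatrix,
    ModelSpec,
    PhenotypeVector,
    SimulationConfig,
    VarianceComponents,
    inflation_factor,
    inflation_report,
    pc_env_covariates,
    scan,
    simulate_dataset,
)
from gxelmm import test_variant as single_test  # avoid pytest collection
from .conftest import make_genotypes


def _vec(ids, vals, cls=PhenotypeVector, **kw):
    return cls(ids, np.asarray(vals, float), **kw)


class TestGlsReducesToOls:
    def test_identity_sigma_matches_statsmodels(self, rng):
        """At Sigma = I the GLS interaction fit is ordinary least squares."""
        n = 200
        ids = [f"s{i}" for i in range(n)]
        x = rng.binomial(2, 0.3, n).astype(float)
        d = rng.binomial(1, 0.5, n).astype(float)
        y = 0.1 * x + rng.standard_normal(n)
        row = single_test(
            _vec(ids, y), x, _vec(ids, d, ExposureVector), ModelSpec(mode="ols")
        )
        X = sm.add_constant(np.column_stack([d, x, d * x]))
        fit = sm.OLS(y, X).fit()
        assert row["beta_snp"] == pytest.approx(fit.params[2], abs=1e-10)
        assert row["gamma_gei"] == pytest.approx(fit.params[3], abs=1e-10)
        assert row["delta_env"] == pytest.approx(fit.params[1], abs=1e-10)
        assert row["p_snp"] == pytest.approx(fit.pvalues[2], abs=1e-10)
        assert row["p_gei"] == pytest.approx(fit.pvalues[3], abs=1e-10)

    def test_six_sample_hand_problem(self):
        """Direct 4x4 normal-equation solve reproduces the estimates."""
        ids = list("abcdef")
        y = np.array([1.0, 2.0, 0.5, 1.5, 3.0, 2.5])
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        d = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        X = np.column_stack([np.ones(6), d, x, d * x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        row = single_test(
            _vec(ids, y), x, _vec(ids, d, ExposureVector), ModelSpec(mode="ols")
        )
        assert row["beta_snp"] == pytest.approx(beta[2], abs=1e-12)
        assert row["gamma_gei"] == pytest.approx(beta[3], abs=1e-12)
        rss = ((y - X @ beta) ** 2).sum()
        s2 = rss / 2  # n - p = 6 - 4
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[3, 3])
        F = (beta[3] / se) ** 2
        assert row["p_gei"] == pytest.approx(stats.f.sf(F, 1, 2), rel=1e-10)


class TestNullCalibration:
    def test_p_gei_uniform_under_correct_sigma(self):
        """With the true covariance supplied, GxE p-values are uniform."""
        cfg = SimulationConfig(n_per_pop=150, m_variants=10_000, seed=31)
        d = simulate_dataset(cfg)
        vc = VarianceComponents(
            names=["genetic", "gxe", "residual"],
            sigma2=np.array(cfg.fractions),
            se=np.zeros(3),
            cov=np.zeros((3, 3)),
            loglik=0.0,
            n_iter=0,
            converged=True,
            boundary=np.zeros(3, bool),
            n=300,
            n_fixed=2,
        )
        spec = ModelSpec(mode="two_re", vc=vc, kinships=[d["K"], d["KD"]])
        res = scan(d["genotypes"], d["phenotype"], d["exposure"], spec)
        ks = stats.kstest(res["p_gei"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_uniform_p_lambda_near_one(self, rng):
        p = rng.uniform(size=100_000)
        assert inflation_factor(p) == pytest.approx(1.0, abs=0.02)


@pytest.fixture(scope="module")
def fitted(small_sim):
    from gxelmm import fit_reml

    d = small_sim
    vc = fit_reml(d["phenotype"], [d["K"], d["KD"]], exposure=d["exposure"])
    spec = ModelSpec(mode="two_re", vc=vc, kinships=[d["K"], d["KD"]])
    return d, spec


class TestScanContracts:
    def test_scan_equals_looped_single_tests(self, fitted):
        d, spec = fitted
        G = d["genotypes"]
        sub = G.dosages[:, :50]
        full = scan(
            type(G)(G.samples, G.variants.iloc[:50], sub),
            d["phenotype"],
            d["exposure"],
            spec,
        )
        for j in (0, 17, 49):
            row = single_test(
                d["phenotype"], sub[:, j], d["exposure"], spec
            )
            for col in ("beta_snp", "gamma_gei", "p_snp", "p_gei"):
                assert row[col] == pytest.approx(full.iloc[j][col], abs=1e-10)

    def test_monomorphic_variant_flagged_not_crashed(self, fitted):
        d, spec = fitted
        G = d["genotypes"]
        dos = G.dosages[:, :10].copy()
        dos[:, 4] = 2.0
        res = scan(
            type(G)(G.samples, G.variants.iloc[:10], dos),
            d["phenotype"],
            d["exposure"],
            spec,
        )
        assert len(res) == 10
        assert np.isnan(res.iloc[4]["p_snp"]) and np.isnan(res.iloc[4]["p_gei"])
        assert np.isfinite(res.drop(index=4)["p_gei"]).all()

    def test_exposure_only_carrier_flagged(self, fitted):
        """A variant carried only by exposed samples makes X_r and D*X_r
        collinear; the row is retained with missing p-values."""
        d, spec = fitted
        G = d["genotypes"]
        dos = G.dosages[:, :5].copy()
        dos[:, 2] = 0.0
        exposed = d["exposure"].values == 1.0
        dos[exposed, 2] = G.dosages[exposed, 2]
        res = scan(
            type(G)(G.samples, G.variants.iloc[:5], dos),
            d["phenotype"],
            d["exposure"],
            spec,
        )
        assert np.isnan(res.iloc[2]["p_gei"])

    def test_variant_order_permutation(self, fitted):
        d, spec = fitted
        G = d["genotypes"]
        res = scan(G, d["phenotype"], d["exposure"], spec)
        perm = np.random.default_rng(3).permutation(G.n_variants)
        Gp = type(G)(G.samples, G.variants.iloc[perm], G.dosages[:, perm])
        resp = scan(Gp, d["phenotype"], d["exposure"], spec)
        merged = res.set_index("variant").loc[resp["variant"]]
        np.testing.assert_allclose(
            merged["p_gei"].to_numpy(), resp["p_gei"].to_numpy(), atol=1e-12
        )

    def test_affine_phenotype_rescaling_keeps_p(self, fitted):
        d, spec = fitted
        y = d["phenotype"]
        y2 = PhenotypeVector(y.samples, 5.0 - 2.0 * y.values)
        x = d["genotypes"].dosages[:, 11]
        r1 = single_test(y, x, d["exposure"], ModelSpec(mode="ols"))
        r2 = single_test(y2, x, d["exposure"], ModelSpec(mode="ols"))
        assert r1["p_snp"] == pytest.approx(r2["p_snp"], rel=1e-10)
        assert r1["p_gei"] == pytest.approx(r2["p_gei"], rel=1e-10)

    def test_two_re_with_zero_gxe_equals_one_re(self, small_sim):
        from gxelmm import fit_reml

        d = small_sim
        vc1 = fit_reml(d["phenotype"], [d["K"]], exposure=d["exposure"])
        vc2 = VarianceComponents(
            names=["genetic", "gxe", "residual"],
            sigma2=np.array([vc1.sigma2[0], 0.0, vc1.sigma2[1]]),
            se=np.zeros(3),
            cov=np.zeros((3, 3)),
            loglik=vc1.loglik,
            n_iter=0,
            converged=True,
            boundary=np.zeros(3, bool),
            n=vc1.n,
            n_fixed=vc1.n_fixed,
        )
        s1 = ModelSpec(mode="one_re", vc=vc1, kinships=[d["K"]])
        s2 = ModelSpec(mode="two_re", vc=vc2, kinships=[d["K"], d["KD"]])
        G = d["genotypes"]
        r1 = scan(G, d["phenotype"], d["exposure"], s1)
        r2 = scan(G, d["phenotype"], d["exposure"], s2)
        np.testing.assert_allclose(
            r1["p_snp"].to_numpy(), r2["p_snp"].to_numpy(), rtol=1e-12
        )


class TestPcEnvCovariates:
    def test_two_block_kinship_analytic_eigenvector(self):
        """For a two-population kinship (within-block 0.5, negative
        between-block entries as in a centered GRM) the leading
        eigenvector is block-constant with opposite signs.

        With between-block exactly 0 and equal block sizes the top
        eigenvalue is degenerate (any rotation of the two block
        indicators is an eigenbasis), so the centered-GRM value -0.2 is
        used to make the eigenvector analytic.
        """
        n = 10
        block = np.repeat([0, 1], n // 2)
        K = np.where(block[:, None] == block[None, :], 0.5, -0.2)
        np.fill_diagonal(K, 1.0)
        ids = [f"s{i}" for i in range(n)]
        Km = KinshipMatrix(ids, K)
        d = np.tile([0.0, 1.0], n // 2)
        cols = pc_env_covariates(Km, ExposureVector(ids, d), 1)
        pc1 = cols[:, 0]
        # eigenvectors of the 2-block matrix are block-constant
        assert np.ptp(pc1[block == 0]) < 1e-10
        assert np.ptp(pc1[block == 1]) < 1e-10
        assert np.sign(pc1[0]) != np.sign(pc1[-1])
        prod = cols[:, 1]
        for b in (0, 1):
            assert len(np.unique(prod[block == b].round(12))) == 2

    def test_constant_exposure_drops_duplicate_products(self, rng):
        n = 20
        A = rng.standard_normal((n, n))
        ids = [f"s{i}" for i in range(n)]
        K = KinshipMatrix(ids, A @ A.T / n)
        D = ExposureVector(ids, np.ones(n))
        cols = pc_env_covariates(K, D, 3)
        assert cols.shape == (n, 3)  # PC_j * 1 duplicates dropped

    def test_k_zero_is_noop(self, rng):
        n = 8
        A = rng.standard_normal((n, n))
        ids = [f"s{i}" for i in range(n)]
        K = KinshipMatrix(ids, A @ A.T / n)
        D = ExposureVector(ids, np.zeros(n))
        assert pc_env_covariates(K, D, 0).shape == (n, 0)
        with pytest.raises(ValueError, match="k <"):
            pc_env_covariates(K, D, n)


class TestInflationFactor:
    def test_median_identity(self):
        chi2 = np.array([0.1, 0.3, 0.4549364231195724, 0.9, 2.0])
        p = stats.chi2.sf(chi2, 1)
        assert inflation_factor(p) == pytest.approx(1.0, rel=1e-10)

    def test_median_homogeneity(self, rng):
        chi2 = stats.chi2.rvs(1, size=5001, random_state=42)
        lam1 = inflation_factor(stats.chi2.sf(chi2, 1))
        lam2 = inflation_factor(stats.chi2.sf(2 * chi2, 1))
        assert lam2 == pytest.approx(2 * lam1, rel=1e-9)

    def test_missing_p_excluded_and_empty_rejected(self):
        assert inflation_factor([0.5, np.nan]) > 0
        with pytest.raises(ValueError, match="p-values"):
            inflation_factor([np.nan])

    def test_report_families_and_qq_arrays(self, small_sim):
        d = small_sim
        res = scan(d["genotypes"], d["phenotype"], d["exposure"], ModelSpec(mode="ols"))
        rep = inflation_report(res)
        assert rep.n_tests == d["genotypes"].n_variants
        assert rep.lambda_snp > 0 and rep.lambda_gei > 0
        assert (np.diff(rep.neglog10_p_gei) <= 1e-12).all()  # sorted descending? ascending
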