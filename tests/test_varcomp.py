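"""REML estimation: oracle equivalence, invariances, calibration."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from gxelmm import (
    ExposureVector,
    KinshipMatrix,
    PhenotypeVector,
    SimulationConfig,
    VarianceComponents,
    fit_reml,
    restricted_loglik,
    simulate_dataset,
    variance_fractions,
)
from gxelmm.varcomp import _ai_reml_dense, _ai_reml_diag
from .conftest import make_genotypes


def error_contrast_loglik(y, X, Sigma):
    """Independent restricted-likelihood oracle.

    Projects y onto an orthonormal basis of the orthogonal complement of
    col(X) and evaluates the multivariate-normal density of the
    contrasts — the definition of the restricted likelihood, sharing no
    code with the AI-REML implementation.
    """
    Q, _ = np.linalg.qr(X, mode="complete")
    A = Q[:, X.shape[1] :]
    w = A.T @ y
    return multivariate_normal(mean=np.zeros(len(w)), cov=A.T @ Sigma @ A).logpdf(w)


@pytest.fixture(scope="module")
def tiny_problem():
    """n=12 two-kinship dataset small enough for exhaustive search."""
    cfg = SimulationConfig(n_per_pop=6, m_variants=300, maf_floor=0.1, seed=9)
    d = simulate_dataset(cfg)
    y = d["phenotype"].values
    n = len(y)
    X = np.column_stack([np.ones(n), d["exposure"].values])
    return y, X, d["K"].values, d["KD"].values, d


class TestGridOracle:
    def test_optimum_matches_exhaustive_grid(self, tiny_problem):
        """AI-REML finds the restricted-likelihood maximum located by a
        dense fraction grid evaluated with the error-contrast MVN oracle."""
        y, X, K, KD, d = tiny_problem
        n = len(y)
        vc = fit_reml(d["phenotype"], [d["K"], d["KD"]], exposure=d["exposure"])
        # profile the total variance on each fraction grid point
        vary = np.var(y, ddof=1)
        best_ll, best_frac = -np.inf, None
        eps = 1e-6
        for fg in np.arange(0.0, 1.0001, 0.01):
            for fd in np.arange(0.0, 1.0001 - fg, 0.01):
                fe = 1.0 - fg - fd
                if fe < 0.005:
                    continue
                frac = np.array([max(fg, eps), max(fd, eps), max(fe, eps)])
                Sigma0 = frac[0] * K + frac[1] * KD + frac[2] * np.eye(n)
                # REML-optimal scale for a fixed shape: s = y'P0y/(n-p)
                try:
                    c0 = np.linalg.cholesky(Sigma0)
                except np.linalg.LinAlgError:
                    continue
                Si = np.linalg.inv(Sigma0)
                XtSiX = X.T @ Si @ X
                P0y = Si @ y - Si @ X @ np.linalg.solve(XtSiX, X.T @ Si @ y)
                s = (y @ P0y) / (n - X.shape[1])
                ll = error_contrast_loglik(y, X, s * Sigma0)
                if ll > best_ll:
                    best_ll, best_frac = ll, frac / frac.sum()
        # constant offset between oracle and implementation conventions
        offset = error_contrast_loglik(
            y, X, vc.sigma2[0] * K + vc.sigma2[1] * KD + vc.sigma2[2] * np.eye(n)
        ) - vc.loglik
        assert vc.loglik + offset >= best_ll - 1e-9
        assert vc.loglik + offset - best_ll < 1e-2  # flat near optimum
        np.testing.assert_allclose(vc.fractions, best_frac, atol=0.02)

    def test_loglik_surface_matches_oracle_shape(self, tiny_problem):
        """restricted_loglik differences equal oracle differences."""
        y, X, K, KD, _ = tiny_problem
        n = len(y)
        rng = np.random.default_rng(0)
        ref = np.array([0.3, 0.3, 0.4])
        base_impl = restricted_loglik(y, X, [K, KD], ref)
        base_orac = error_contrast_loglik(
            y, X, ref[0] * K + ref[1] * KD + ref[2] * np.eye(n)
        )
        for _ in range(10):
            th = rng.uniform(0.05, 1.0, 3)
            d_impl = restricted_loglik(y, X, [K, KD], th) - base_impl
            d_orac = (
                error_contrast_loglik(
                    y, X, th[0] * K + th[1] * KD + th[2] * np.eye(n)
                )
                - base_orac
            )
            assert d_impl == pytest.approx(d_orac, abs=1e-8)


class TestPathEquivalence:
    def test_dense_and_eigen_paths_agree(self, rng):
        n = 60
        G = make_genotypes(n, 400, rng)
        from gxelmm import compute_grm

        K = compute_grm(G).values
        L = np.linalg.cholesky(0.5 * K + 0.5 * np.eye(n))
        y = L @ rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.binomial(1, 0.5, n)])
        r_dense = _ai_reml_dense(y, X, [K], 1e-8, 1e-6, 100)
        r_diag = _ai_reml_diag(y, X, K, 1e-8, 1e-6, 100)
        np.testing.assert_allclose(r_dense["sigma2"], r_diag["sigma2"], rtol=1e-4)
        assert r_dense["loglik"] == pytest.approx(r_diag["loglik"], abs=1e-6)


class TestInvariances:
    def test_rescaling_phenotype_scales_components(self, small_sim):
        d = small_sim
        vc1 = fit_reml(d["phenotype"], [d["K"], d["KD"]], exposure=d["exposure"])
        y2 = PhenotypeVector(d["phenotype"].samples, 3.0 * d["phenotype"].values)
        vc2 = fit_reml(y2, [d["K"], d["KD"]], exposure=d["exposure"])
        np.testing.assert_allclose(vc2.sigma2, 9.0 * vc1.sigma2, rtol=1e-3)
        np.testing.assert_allclose(vc2.fractions, vc1.fractions, atol=1e-4)

    def test_fractions_sum_to_one(self, small_sim):
        d = small_sim
        vc = fit_reml(d["phenotype"], [d["K"], d["KD"]], exposure=d["exposure"])
        assert vc.fractions.sum() == pytest.approx(1.0, abs=1e-10)


class TestNullCalibration:
    def test_iid_phenotype_gives_boundary_heritability(self, rng):
        """With no genetic signal the fitted genetic fraction piles up
        near zero for unrelated samples.

        The GRM sampling noise gives SE(sigma_g^2) ~ sqrt(2 m)/n, so at
        n=500, m=250 the half-normal exceedance P(fraction > 0.1) is
        about 1% and the 95% concentration claim holds with margin.
        """
        n = 500
        G = make_genotypes(n, 250, rng)
        from gxelmm import compute_grm

        K = compute_grm(G)
        small = 0
        reps = 100
        for _ in range(reps):
            y = PhenotypeVector(K.samples, rng.standard_normal(n))
            vc = fit_reml(y, [K])
            if vc.fractions[0] < 0.1:
                small += 1
        assert small >= 0.95 * reps


class TestFractions:
    def test_normalized_components_passthrough(self):
        vc = _manual_vc([0.4, 0.2, 0.4])
        np.testing.assert_allclose(vc.fractions, [0.4, 0.2, 0.4])

    def test_unnormalized_components(self):
        vc = _manual_vc([2.0, 1.0, 1.0])
        np.testing.assert_allclose(vc.fractions, [0.5, 0.25, 0.25])

    def test_delta_method_matches_hand_derivation(self):
        """Two components (a, b) with diagonal covariance: the fraction
        f = a/(a+b) has Var(f) = (b Va^.5)^2 + (a Vb^.5)^2 over (a+b)^4."""
        a, b, va, vb = 1.2, 0.8, 0.09, 0.04
        vc = VarianceComponents(
            names=["genetic", "residual"],
            sigma2=np.array([a, b]),
            se=np.sqrt([va, vb]),
            cov=np.diag([va, vb]),
            loglik=0.0,
            n_iter=1,
            converged=True,
            boundary=np.array([False, False]),
            n=100,
            n_fixed=1,
        )
        S = a + b
        expected_se = np.sqrt((b**2 * va + a**2 * vb) / S**4)
        table = variance_fractions(vc)
        assert table["fraction_se"][0] == pytest.approx(expected_se, rel=1e-12)
        assert table["fraction_se"][1] == pytest.approx(expected_se, rel=1e-12)

    def test_zero_total_variance_rejected(self):
        vc = _manual_vc([0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="total variance"):
            variance_fractions(vc)


def _manual_vc(sigma2):
    sigma2 = np.asarray(sigma2, float)
    q = len(sigma2)
    return VarianceComponents(
        names=["genetic", "gxe", "residual"][:q],
        sigma2=sigma2,
        se=np.zeros(q),
        cov=np.zeros((q, q)),
        loglik=0.0,
        n_iter=1,
        converged=True,
        boundary=np.zeros(q, bool),
        n=50,
        n_fixed=2,
    )


class TestRecoverySpread:
    def test_bias_small_and_spread_grows_with_gxe_variance(self):
        """Implanted GxE variance is recovered with little bias and the
        estimator spread increases with the implanted value."""
        sds = {}
        for sd2 in (0.05, 0.2):
            cfg = SimulationConfig(
                n_per_pop=250,
                m_variants=1500,
                sigma_g2=0.4,
                sigma_d2=sd2,
                sigma_e2=round(0.6 - sd2, 10),
                seed=77,
            )
            est = []
            for ss in np.random.SeedSequence(cfg.seed).spawn(8):
                d = simulate_dataset(cfg, np.random.default_rng(ss))
                vc = fit_reml(
                    d["phenotype"], [d["K"], d["KD"]], exposure=d["exposure"]
                )
                est.append(vc.fractions[1])
            est = np.array(est)
            se = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - sd2) < 3 * se + 0.02
            sds[sd2] = est.std(ddof=1)
        assert sds[0.2] > sds[0.05]
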