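"""Mixed-model solvers against closed forms and dense-inversion oracles."""

import numpy as np
import pandas as pd
import pytest

import phenogs as pg
from phenogs.mixed_models import (
    conditional_multitrait_blup,
    fit_multitrait_em,
)


def random_instance(seed, n=30, m=50):
    rng = np.random.default_rng(seed)
    Z = rng.integers(0, 3, size=(n, m)).astype(float)
    Z -= Z.mean(axis=0)
    g = Z @ rng.normal(0, 0.1, m)
    y = 2.0 + g + rng.normal(0, 0.5, n)
    return y, Z


class TestRRBLUP:
    def test_two_line_hand_inversion(self):
        """y=(1,-1), z=(1,-1), lam=1: u = z'(zz'+I)^-1 y = 2/3."""
        u, gebv = pg.solve_rrblup(np.array([1.0, -1.0]),
                                  np.array([[1.0], [-1.0]]), 1.0)
        assert u[0] == pytest.approx(2.0 / 3.0, abs=1e-12)
        np.testing.assert_allclose(gebv, [2.0 / 3.0, -2.0 / 3.0], atol=1e-12)

    def test_infinite_shrinkage_kills_effects(self):
        y, Z = random_instance(0)
        u, _ = pg.solve_rrblup(y, Z, 1e12)
        assert np.abs(u).max() < 1e-6 * y.std()

    def test_nonpositive_ridge_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pg.solve_rrblup(np.array([1.0, 2.0]), np.eye(2), 0.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_marker_form_equals_gblup_form(self, seed):
        """u = Z'(ZZ'+lam I)^-1 y  <=>  g = K(K+delta I)^-1 y, K=ZZ'/c."""
        y, Z = random_instance(seed)
        lam = 2.5
        c = 7.0
        _, gebv_marker = pg.solve_rrblup(y, Z, lam)
        K = Z @ Z.T / c
        yc = y - y.mean()
        gebv_K = K @ np.linalg.solve(K + (lam / c) * np.eye(len(y)), yc)
        np.testing.assert_allclose(gebv_marker, gebv_K, atol=1e-8)


class TestREML:
    def test_optimum_beats_thousand_point_grid(self):
        y, Z = random_instance(4)
        K = Z @ Z.T
        vc = pg.reml_single_trait(y, K=K)

        # independent profiled-likelihood oracle on a dense grid
        n = len(y)
        X = np.ones((n, 1))
        S = np.eye(n) - X @ X.T / n
        w, U = np.linalg.eigh(S @ K @ S)
        xi, eta = w[-(n - 1):], (U[:, -(n - 1):].T @ y)
        q = n - 1

        def ll(log_d):
            d = np.exp(log_d)
            ss = (eta**2 / (xi + d)).sum()
            return 0.5 * (q * (np.log(q / (2 * np.pi)) - 1 - np.log(ss))
                          - np.log(xi + d).sum())

        grid = np.array([ll(g) for g in np.linspace(-10, 10, 1000)])
        assert vc.loglik >= grid.max() - 1e-6

    def test_pure_noise_estimates_near_zero_and_boundary_flagged(self):
        """With no genetic signal sigma2_a sits at or near zero; the
        zero-variance boundary is flagged, never raised.  The estimate
        is a boundary case, so over several noise draws the average
        heritability must be tiny and the flag must fire."""
        rng = np.random.default_rng(5)
        _, Z = random_instance(5, n=200, m=400)
        K = Z @ Z.T / Z.shape[1]
        h2s, flags = [], []
        for _ in range(5):
            vc = pg.reml_single_trait(rng.normal(0, 1, 200), K=K)
            h2s.append(vc.h2)
            flags.append(vc.at_boundary)
        assert np.mean(h2s) < 0.1
        assert any(flags)

    def test_constant_response_errors(self):
        with pytest.raises(ValueError, match="zero residual"):
            pg.reml_single_trait(np.full(20, 3.0), K=np.eye(20))

    def test_estimates_invariant_to_constant_shift(self):
        y, Z = random_instance(6)
        K = Z @ Z.T
        a = pg.reml_single_trait(y, K=K)
        b = pg.reml_single_trait(y + 1000.0, K=K)
        assert a.sigma2_a == pytest.approx(b.sigma2_a, rel=1e-5)
        assert a.sigma2_e == pytest.approx(b.sigma2_e, rel=1e-5)


def gls_oracle(y, X, K, sigma2_a, sigma2_e):
    """Direct dense inversion of the mixed model: beta by GLS, g by BLUP."""
    V = sigma2_a * K + sigma2_e * np.eye(len(y))
    Vi = np.linalg.inv(V)
    beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
    g = sigma2_a * K @ Vi @ (y - X @ beta)
    return beta, g


class TestCovariateGS:
    def test_matches_direct_inversion_oracle(self):
        rng = np.random.default_rng(7)
        y, Z = random_instance(7)
        K = Z @ Z.T / Z.shape[1]
        X_sri = rng.normal(0, 1, (len(y), 2))
        fit = pg.fit_covariate_gs(y, X_sri, K)
        X = np.column_stack([np.ones(len(y)), X_sri])
        beta_o, g_o = gls_oracle(y, X, K, fit.vc.sigma2_a, fit.vc.sigma2_e)
        np.testing.assert_allclose(fit.beta, beta_o, atol=1e-8)
        np.testing.assert_allclose(fit.gebv_train, g_o, atol=1e-8)

    def test_unigs_matches_oracle_too(self):
        y, Z = random_instance(8)
        K = Z @ Z.T / Z.shape[1]
        fit = pg.fit_gblup(y, K)
        beta_o, g_o = gls_oracle(y, np.ones((len(y), 1)), K,
                                 fit.vc.sigma2_a, fit.vc.sigma2_e)
        np.testing.assert_allclose(fit.gebv_train, g_o, atol=1e-8)

    def test_vanishing_noise_covariate_coefficient_recovered(self):
        """True coefficient 2.0 recovered as residual noise vanishes.

        An exactly noiseless response has zero residual variation after
        projection, which REML treats as a hard degeneracy, so the check
        runs at negligible (1e-8) noise instead.
        """
        rng = np.random.default_rng(9)
        n = 40
        x = rng.normal(0, 1, n)
        y = 1.0 + 2.0 * x + rng.normal(0, 1e-8, n)
        fit = pg.fit_covariate_gs(y, x[:, None], np.eye(n))
        assert fit.beta[1] == pytest.approx(2.0, abs=1e-6)

    def test_exactly_noiseless_response_is_a_hard_error(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 40)
        with pytest.raises(ValueError, match="zero residual"):
            pg.fit_covariate_gs(1.0 + 2.0 * x, x[:, None], np.eye(40))

    def test_collinear_covariates_named_in_error(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 30)
        X = np.column_stack([x, x])
        with pytest.raises(ValueError, match="NDVI_copy"):
            pg.fit_covariate_gs(np.arange(30.0), X, np.eye(30),
                                sri_names=["NDVI", "NDVI_copy"])

    def test_prediction_invariant_to_response_shift(self):
        y, Z = random_instance(11)
        K = Z @ Z.T / Z.shape[1]
        a = pg.fit_gblup(y, K).gebv_train
        b = pg.fit_gblup(y + 50.0, K).gebv_train
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestSRIRegression:
    def test_noiseless_single_index_recovery(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (50, 3))
        y = 0.5 + 2.0 * X[:, 0]
        fit = pg.fit_sri_regression(y, X)
        np.testing.assert_allclose(fit.coef.to_numpy(),
                                   [0.5, 2.0, 0.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)

    def test_intercept_only_predicts_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        fit = pg.fit_sri_regression(y, np.zeros((4, 0)))
        np.testing.assert_allclose(fit.fitted, y.mean())

    def test_duplicated_index_column_errors(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 30)
        with pytest.raises(ValueError, match="rank deficient"):
            pg.fit_sri_regression(np.arange(30.0),
                                  np.column_stack([x, x]))

    def test_too_few_lines_errors(self):
        with pytest.raises(ValueError, match="need n"):
            pg.fit_sri_regression(np.arange(3.0), np.zeros((3, 3)))


def dense_multitrait_oracle(Y, G, H, R):
    """Conditional BLUP via explicit trait-major Kronecker matrices."""
    n, t = Y.shape
    Vfull = np.kron(H, G) + np.kron(R, np.eye(n))
    yv = Y.T.ravel()            # trait-major stacking
    obs = ~np.isnan(yv)
    V = Vfull[np.ix_(obs, obs)]
    Xfull = np.kron(np.eye(t), np.ones((n, 1)))
    X = Xfull[obs][:, np.asarray(~np.isnan(Y).all(axis=0))]
    Vi = np.linalg.inv(V)
    beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ yv[obs]
    Cgy = np.kron(H, G)[:, obs]
    g = Cgy @ Vi @ (yv[obs] - X @ beta)
    return g.reshape(t, n).T


@pytest.fixture(scope="module")
def biv(bivariate_study):
    cfg, wide, grm, truth = bivariate_study
    return wide, grm.values, truth


class TestMultiTrait:

    def test_em_loglik_is_monotone(self, biv):
        wide, G, _ = biv
        vc = fit_multitrait_em(wide.to_numpy(), G)
        ll = vc.loglik_path
        diffs = np.diff(ll)
        assert (diffs >= -1e-8 * (np.abs(ll[:-1]) + 1.0)).all()

    def test_genetic_correlation_recovered(self, biv):
        wide, G, truth = biv
        vc = fit_multitrait_em(wide.to_numpy(), G, traits=["A", "B"])
        r, clamped = vc.genetic_correlation("A", "B")
        assert not clamped
        assert r == pytest.approx(
            truth.realized_genetic_corr.loc["A", "B"], abs=0.12
        )

    def test_duplicate_trait_drives_r_to_one(self, biv):
        wide, G, _ = biv
        sub = wide.iloc[:150]
        Y = np.column_stack([sub["A"], sub["A"]])
        vc = fit_multitrait_em(Y, G[:150, :150], max_iter=100)
        r, _ = vc.genetic_correlation()
        assert r > 0.99

    def test_conditional_blup_matches_dense_kronecker_oracle(self):
        rng = np.random.default_rng(14)
        n, t = 25, 2
        A = rng.normal(0, 1, (n, n))
        G = A @ A.T / n + 0.5 * np.eye(n)
        H = np.array([[1.0, 0.6], [0.6, 1.5]])
        R = np.array([[0.8, 0.2], [0.2, 0.6]])
        Y = rng.normal(0, 1, (n, t))
        Y[-5:, 0] = np.nan      # five lines missing the primary trait
        gebv, _ = conditional_multitrait_blup(Y, G, H, R)
        np.testing.assert_allclose(
            gebv, dense_multitrait_oracle(Y, G, H, R), atol=1e-8
        )

    def test_diagonal_truth_reduces_to_univariate_gblup(self):
        cfg = pg.SimulationConfig(
            n_families=10, lines_per_family=20, n_markers=500,
            n_chromosomes=5, n_environments=1, trait_names=("A", "B"),
            target_h2={"A": 0.5, "B": 0.5}, genetic_corr=np.eye(2),
            residual_corr=np.eye(2), seed=15,
        )
        m = pg.simulate_nam_genotypes(cfg)
        tab, _ = pg.simulate_traits(m, cfg)
        G = pg.compute_grm(pg.impute_missing(m)).values
        wide = tab.pivot_table(index="genotype_id", columns="trait",
                               values="value").loc[m.line_ids]
        mv = pg.fit_multitrait_gs(wide, G)
        uv = pg.fit_gblup(wide["A"].to_numpy(), G)
        r = np.corrcoef(mv.gebv["A"], uv.gebv_train)[0, 1]
        assert 1.0 - r < 0.02

    def test_single_trait_reduces_exactly_to_univariate_path(self, biv):
        wide, G, _ = biv
        sub = wide.iloc[:120]
        mv = pg.fit_multitrait_gs(sub[["A"]], G[:120, :120])
        uv = pg.fit_gblup(sub["A"].to_numpy(), G[:120, :120])
        np.testing.assert_allclose(mv.gebv["A"].to_numpy(), uv.gebv_train,
                                   atol=1e-10)
        assert mv.vc.H[0, 0] == pytest.approx(uv.vc.sigma2_a)

    def test_zero_variance_trait_errors(self):
        Y = np.column_stack([np.arange(40.0), np.full(40, 2.0)])
        with pytest.raises(ValueError, match="zero variance"):
            fit_multitrait_em(Y, np.eye(40))

    def test_partial_records_transfer_secondary_information(self, biv):
        """Lines missing the primary trait but observed for a correlated
        secondary get better predictions than from kinship alone."""
        wide, G, truth = biv
        Y = wide.to_numpy().copy()
        test = np.arange(400, 500)
        y_true = Y[test, 0].copy()
        Y[test, 0] = np.nan
        fit = pg.fit_multitrait_gs(
            pd.DataFrame(Y, index=wide.index, columns=["A", "B"]), G
        )
        r_mv = np.corrcoef(fit.gebv.iloc[test, 0], y_true)[0, 1]
        train = np.arange(0, 400)
        uv = pg.fit_gblup(Y[train, 0], G[np.ix_(train, train)])
        r_uv = np.corrcoef(uv.predict(G[np.ix_(test, train)]), y_true)[0, 1]
        assert r_mv > r_uv
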