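import numpy as np
import pytest

from hatcv.crossval import kfold_cv, make_folds
from hatcv.hat import (HatRandom, gcv_gress, hat_fixed, hat_mixed,
                       hat_random, predictability_at_lambda, press_kfold,
                       press_loo, tune_lambda)
from hatcv.kinship import eigendecompose
from hatcv.reml import blue_blup
from hatcv.synthetic import SimulationSpec, simulate_dataset


def _random_psd(n, rank, seed):
    rng = np.random.default_rng(seed)
    B = rng.standard_normal((n, rank))
    A = B @ B.T
    return A * n / np.trace(A)


class TestHatFixed:
    def test_idempotent_and_trace_p(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 3))
        W = _random_psd(25, 25, 5) + np.eye(25)
        for w in (None, W):
            H = hat_fixed(X, w)
            np.testing.assert_allclose(H @ H, H, atol=1e-10)
            assert np.trace(H) == pytest.approx(3.0, abs=1e-10)

    def test_mean_model_leverages(self):
        H = hat_fixed(np.ones((3, 1)))
        np.testing.assert_allclose(H, np.full((3, 3), 1 / 3), atol=1e-12)

    def test_singular_design_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="singular"):
            hat_fixed(X)


class TestHatRandom:
    def test_identity_kinship_half_leverage(self):
        hr = hat_random(eigendecompose(np.eye(5)), lam=1.0)
        np.testing.assert_allclose(hr.diagonal(), 0.5)
        np.testing.assert_allclose(hr.full(), 0.5 * np.eye(5), atol=1e-12)

    def test_shrinkage_limit_large_lambda(self, fixture60):
        _, kin, _, _, _ = fixture60
        hr = hat_random(kin, lam=1e9)
        assert hr.diagonal().max() < 1e-6

    def test_eigen_route_equals_explicit_inverse(self):
        """U diag(d/(d+lam)) U' equals sigma_xi^2 A (A sigma_xi^2 +
        I sigma^2)^-1 formed explicitly."""
        A = _random_psd(40, 22, 8)
        kin = eigendecompose(A.copy())
        sigma_xi2, sigma2 = 1.7, 0.9
        lam = sigma2 / sigma_xi2
        explicit = sigma_xi2 * A @ np.linalg.inv(
            A * sigma_xi2 + np.eye(40) * sigma2)
        hr = hat_random(kin, lam)
        np.testing.assert_allclose(hr.full(), explicit, atol=1e-10)
        np.testing.assert_allclose(hr.diagonal(), np.diag(explicit),
                                   atol=1e-10)

    def test_block_matches_full(self, fixture60):
        _, kin, _, _, _ = fixture60
        hr = hat_random(kin, 1.3)
        idx = np.array([3, 10, 41])
        np.testing.assert_allclose(hr.block(idx),
                                   hr.full()[np.ix_(idx, idx)], atol=1e-12)

    def test_trace_is_effective_df_monotone_in_lambda(self, fixture60):
        _, kin, _, _, _ = fixture60
        traces = [hat_random(kin, lam).trace() for lam in (0.1, 1, 10)]
        assert traces[0] > traces[1] > traces[2]
        np.testing.assert_allclose(
            traces[1], np.sum(kin.D / (kin.D + 1.0)), atol=1e-12)

    def test_nonpositive_lambda_rejected(self, fixture60):
        _, kin, _, _, _ = fixture60
        for lam in (0.0, -2.0):
            with pytest.raises(ValueError):
                hat_random(kin, lam)


class TestHatMixed:
    def test_limits(self):
        rng = np.random.default_rng(12)
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        HF = hat_fixed(X)
        n = 10
        np.testing.assert_allclose(hat_mixed(HF, np.zeros((n, n))), HF)
        np.testing.assert_allclose(hat_mixed(HF, np.eye(n)), np.eye(n),
                                   atol=1e-12)

    def test_maps_y_to_fitted_values(self):
        """H_M y = X beta_hat + xi_hat when H_F uses the V^-1 weight."""
        geno, kin, pheno, _ = simulate_dataset(
            SimulationSpec(n=30, m=80, h2=0.5, seed=21))
        kin = kin.require_eigen()
        y = pheno["y"].to_numpy()
        X = np.ones((30, 1))
        lam = 1.5
        beta, xi_hat = blue_blup(y, X, kin, lam)
        Vinv = np.linalg.inv(kin.A + lam * np.eye(30))
        HM = hat_mixed(hat_fixed(X, Vinv), hat_random(kin, lam))
        np.testing.assert_allclose(HM @ y, X @ beta + xi_hat, atol=1e-8)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            hat_mixed(np.eye(3), np.eye(4))


class TestPressLoo:
    def test_hand_example(self):
        res = press_loo([1.0, 1.0], [0.5, 0.5], ss=10.0)
        assert res.press == pytest.approx(8.0)

    def test_zero_leverage_gives_eress(self):
        e = np.array([1.0, -2.0, 0.5])
        res = press_loo(e, np.zeros(3), ss=1.0)
        assert res.press == pytest.approx(float(e @ e))

    def test_saturated_leverage_names_observation(self):
        with pytest.raises(ValueError, match="observation 1"):
            press_loo([1.0, 1.0], [0.2, 1.0 - 1e-12], ss=1.0)

    def test_matches_delete_one_refit(self, fixture60, fit60):
        """Leverage-corrected residuals equal brute-force leave-one-out
        BLUP refits at fixed lambda and whole-sample beta."""
        _, kin, y, X, _ = fixture60
        lam = fit60.lambda_hat
        hr = hat_random(kin, lam)
        e_hat = fit60.xi_obs - fit60.xi_hat
        res = press_loo(e_hat, hr.diagonal(), xi=fit60.xi_obs, lam=lam)
        xi = fit60.xi_obs
        n = y.size
        for j in [0, 17, 59]:
            keep = np.delete(np.arange(n), j)
            pred = kin.A[j, keep] @ np.linalg.solve(
                kin.A[np.ix_(keep, keep)] + lam * np.eye(n - 1), xi[keep])
            assert res.residuals_pred[j] == pytest.approx(xi[j] - pred,
                                                          abs=1e-8)


class TestPressKfold:
    def test_k_equals_n_reduces_to_loo(self, fixture60, fit60):
        _, kin, y, X, _ = fixture60
        lam = fit60.lambda_hat
        hr = hat_random(kin, lam)
        e_hat = fit60.xi_obs - fit60.xi_hat
        loo = press_loo(e_hat, hr.diagonal(), xi=fit60.xi_obs)
        folds = make_folds(y.size, y.size, seed=0)
        kf = press_kfold(e_hat, hr, folds, xi=fit60.xi_obs)
        assert kf.press == pytest.approx(loo.press, abs=1e-12)
        np.testing.assert_allclose(kf.residuals_pred, loo.residuals_pred,
                                   atol=1e-12)

    def test_fixed_model_mean_only_toy(self):
        """y = (0, 0, 3) under the mean model: PRESS = 13.5, and the
        corrected residual for observation 3 equals the delete-one
        refit's prediction error."""
        y = np.array([0.0, 0.0, 3.0])
        X = np.ones((3, 1))
        H = hat_fixed(X)
        e_hat = y - H @ y
        folds = make_folds(3, 3, seed=0)
        res = press_kfold(e_hat, H, folds, W=np.eye(3), ss=6.0)
        assert res.press == pytest.approx(13.5)
        # deleting obs 3: training mean 0, predicted residual 3 - 0 = 3
        assert sorted(np.round(res.residuals_pred, 10)) == [-1.5, -1.5, 3.0]

    def test_matches_fold_deletion_refit(self):
        """K-fold corrected residuals equal brute-force fold-deletion
        BLUP refits at fixed lambda and whole-sample beta (n=40, K=5)."""
        geno, kin, pheno, _ = simulate_dataset(
            SimulationSpec(n=40, m=120, h2=0.5, seed=33))
        kin = kin.require_eigen()
        y = pheno["y"].to_numpy()
        X = np.ones((40, 1))
        lam = 2.0
        beta, xi_hat = blue_blup(y, X, kin, lam)
        xi = y - X @ beta
        e_hat = xi - xi_hat
        folds = make_folds(40, 5, seed=3)
        res = press_kfold(e_hat, hat_random(kin, lam), folds, xi=xi)
        oracle = kfold_cv(y, X, kin, folds, reestimate=False,
                          lambda_fixed=lam, beta_fixed=beta)
        np.testing.assert_allclose(res.residuals_pred,
                                   oracle.residuals_pred, atol=1e-8)
        assert res.press == pytest.approx(oracle.press, rel=1e-10)


class TestGcv:
    def test_equals_loo_when_leverages_equal(self):
        """A = I gives identical leverages, so GRESS = LOO PRESS."""
        rng = np.random.default_rng(14)
        kin = eigendecompose(np.eye(12))
        hr = hat_random(kin, lam=0.8)
        e_hat = rng.standard_normal(12)
        loo = press_loo(e_hat, hr.diagonal(), ss=5.0)
        gcv = gcv_gress(e_hat, hr, ss=5.0)
        assert gcv.press == pytest.approx(loo.press, rel=1e-12)

    def test_matrix_form_equals_scalar_form(self, fixture60, fit60):
        _, kin, _, _, _ = fixture60
        hr = hat_random(kin, fit60.lambda_hat)
        e_hat = fit60.xi_obs - fit60.xi_hat
        res = gcv_gress(e_hat, hr, xi=fit60.xi_obs)
        n = e_hat.size
        denom = (np.trace(np.eye(n) - hr.full()) / n) ** 2
        assert res.press == pytest.approx(float(e_hat @ e_hat) / denom,
                                          rel=1e-12)

    def test_zero_mean_leverage_gives_eress(self):
        hr = HatRandom(lam=1.0, U=np.eye(4), shrink=np.zeros(4))
        e = np.array([1.0, 2.0, 0.0, -1.0])
        res = gcv_gress(e, hr, ss=9.0)
        assert res.press == pytest.approx(float(e @ e))


class TestTuneLambda:
    def test_dominates_reml_estimate(self, fixture60, fit60):
        _, kin, y, X, _ = fixture60
        for obj in ("hat_loo", "gcv"):
            lam, r2_max, _ = tune_lambda(y, X, kin, objective=obj,
                                         fit=fit60)
            r2_reml = predictability_at_lambda(fit60.xi_obs, kin,
                                               fit60.lambda_hat, obj)
            assert r2_max >= r2_reml - 1e-12

    def test_refined_optimum_matches_dense_grid(self, fixture60, fit60):
        _, kin, y, X, _ = fixture60
        lam, r2_max, _ = tune_lambda(y, X, kin, fit=fit60)
        dense = np.logspace(np.log10(fit60.lambda_hat) - 1,
                            np.log10(fit60.lambda_hat) + 1, 1000)
        r2s = [predictability_at_lambda(fit60.xi_obs, kin, g, "hat_loo")
               for g in dense]
        i = int(np.argmax(r2s))
        spacing = np.log(dense[1]) - np.log(dense[0])
        assert r2_max >= r2s[i] - 1e-9
        assert abs(np.log(lam) - np.log(dense[i])) <= spacing

    def test_predictability_vanishes_at_huge_lambda(self, fit60, fixture60):
        """As lambda grows the BLUP shrinks to the mean and R^2 -> ~0."""
        _, kin, _, _, _ = fixture60
        r2 = predictability_at_lambda(fit60.xi_obs, kin, 1e8, "hat_loo")
        assert abs(r2) < 0.05
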