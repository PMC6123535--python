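"""Learner contracts against independent oracles: LOOCV-of-mean identity,
ridge normal equations, lasso KKT / soft-thresholding, tree splits, the SVR
epsilon tube, error metrics, and Wilcoxon comparisons."""

import numpy as np
import pandas as pd
import pytest
from sklearn.preprocessing import StandardScaler

from icerec.predictive_models import (
    CVResult,
    compare_to_reference,
    default_grid,
    fit_lasso,
    fit_mean_reference,
    fit_ols,
    fit_ridge,
    fit_svr,
    fit_tree,
    loocv,
    mae,
    rmse,
    select_features_lasso,
)


def _linear_data(n=30, p=4, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = 1.5 + X @ beta + noise * rng.standard_normal(n)
    return X, y, beta


class TestMeanReference:
    def test_constant_prediction(self):
        fit = fit_mean_reference([1.0, 2.0, 3.0])
        np.testing.assert_allclose(fit.predict(np.zeros((5, 2))), 2.0)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            fit_mean_reference([])

    def test_loocv_matches_algebraic_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            y = rng.standard_normal(rng.integers(5, 40))
            cv = loocv("mean_ref", np.zeros((len(y), 1)), y)
            expected = (y.sum() - y) / (len(y) - 1)
            np.testing.assert_allclose(cv.predictions, expected, atol=1e-10)

    def test_constant_target_zero_loocv_error(self):
        y = np.full(10, 4.2)
        cv = loocv("mean_ref", np.zeros((10, 1)), y)
        assert cv.mae == 0.0 and cv.rmse == 0.0


class TestOls:
    def test_noiseless_interpolation(self):
        X, y, _ = _linear_data(noise=0.0)
        fit = fit_ols(X, y)
        np.testing.assert_allclose(fit.predict(X), y, atol=1e-8)

    def test_three_point_line(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = 2.0 * X[:, 0] + 1.0
        fit = fit_ols(X, y)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-10)

    def test_p_ge_n_rejected(self):
        X = np.random.default_rng(0).standard_normal((5, 5))
        with pytest.raises(ValueError, match="fewer features"):
            fit_ols(X, np.ones(5))

    def test_rank_deficiency_warns(self):
        X = np.ones((10, 2))
        X[:, 1] = 2 * X[:, 0]  # collinear
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.warns(UserWarning, match="rank"):
            fit_ols(X, np.arange(10.0))


class TestRidge:
    def test_lambda_zero_equals_ols(self):
        X, y, _ = _linear_data(noise=0.3, seed=4)
        pred_ridge = fit_ridge(X, y, 0.0).predict(X)
        pred_ols = fit_ols(X, y).predict(X)
        np.testing.assert_allclose(pred_ridge, pred_ols, atol=1e-8)

    def test_huge_lambda_shrinks_to_mean(self):
        X, y, _ = _linear_data(noise=0.3, seed=5)
        pred = fit_ridge(X, y, 1e9).predict(X)
        np.testing.assert_allclose(pred, y.mean(), atol=1e-5)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        lam = 1.0
        fit = fit_ridge(X, y, lam)
        Xs = StandardScaler().fit_transform(X)
        beta = np.linalg.solve(Xs.T @ Xs + lam * np.eye(3), Xs.T @ (y - y.mean()))
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            fit_ridge(np.zeros((3, 1)), np.ones(3), -1.0)


class TestLasso:
    def test_lambda_zero_equals_ols(self):
        X, y, _ = _linear_data(n=25, p=3, noise=0.2, seed=7)
        np.testing.assert_allclose(
            fit_lasso(X, y, 0.0).predict(X), fit_ols(X, y).predict(X), atol=1e-8
        )

    def test_lambda_above_kkt_max_gives_all_zero_slopes(self):
        X, y, _ = _linear_data(n=40, p=5, noise=0.5, seed=8)
        Xs = StandardScaler().fit_transform(X)
        lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y)
        fit = fit_lasso(X, y, lam_max * 1.0001)
        np.testing.assert_allclose(fit.coefficients, 0.0, atol=1e-12)
        # just below lambda_max at least one slope activates
        fit2 = fit_lasso(X, y, lam_max * 0.95)
        assert np.any(fit2.coefficients != 0.0)

    def test_orthonormal_design_soft_thresholds_ols(self):
        rng = np.random.default_rng(9)
        n, p = 32, 4
        G = rng.standard_normal((n, p))
        G -= G.mean(axis=0)
        Q, _ = np.linalg.qr(G)  # zero-mean orthonormal columns
        X = Q * np.sqrt(n)  # unit variance (ddof=0), X.T @ X = n * I
        y = rng.standard_normal(n)
        lam = 0.05
        beta_ols = X.T @ (y - y.mean()) / n
        expected = np.sign(beta_ols) * np.maximum(np.abs(beta_ols) - lam, 0.0)
        fit = fit_lasso(X, y, lam)
        np.testing.assert_allclose(fit.coefficients, expected, atol=1e-7)


class TestTree:
    def test_constant_target_single_leaf(self):
        X = np.arange(10.0).reshape(-1, 1)
        fit = fit_tree(X, np.full(10, 3.0), max_depth=3, min_samples_leaf=1)
        np.testing.assert_allclose(fit.predict(X), 3.0)
        assert fit.estimator.get_n_leaves() == 1

    def test_depth_one_recovers_step_threshold(self):
        X = np.arange(20.0).reshape(-1, 1)
        y = (X[:, 0] >= 12).astype(float) * 10.0
        fit = fit_tree(X, y, max_depth=1, min_samples_leaf=1)
        threshold = fit.estimator.tree_.threshold[0]
        assert 11.0 < threshold < 12.0  # between the flanking data points
        np.testing.assert_allclose(fit.predict(X), y)

    def test_min_leaf_n_predicts_mean(self):
        X = np.arange(8.0).reshape(-1, 1)
        y = np.arange(8.0)
        fit = fit_tree(X, y, max_depth=5, min_samples_leaf=8)
        np.testing.assert_allclose(fit.predict(X), y.mean())


class TestSvr:
    def test_constant_target_within_tube(self):
        X = np.random.default_rng(10).standard_normal((15, 2))
        y = np.full(15, 2.0)
        fit = fit_svr(X, y, C=1.0, epsilon=0.1, kernel="rbf")
        assert np.all(np.abs(fit.predict(X) - 2.0) <= 0.1 + 1e-6)

    def test_linear_kernel_noiseless_within_tube(self):
        X, y, _ = _linear_data(n=40, p=3, noise=0.0, seed=11)
        fit = fit_svr(X, y, C=1000.0, epsilon=0.05, kernel="linear")
        assert np.max(np.abs(fit.predict(X) - y)) <= 0.05 + 1e-3

    def test_deterministic(self):
        X, y, _ = _linear_data(n=30, p=3, noise=0.2, seed=12)
        p1 = fit_svr(X, y, C=10.0, epsilon=0.1, kernel="rbf").predict(X)
        p2 = fit_svr(X, y, C=10.0, epsilon=0.1, kernel="rbf").predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            fit_svr(np.zeros((3, 1)), np.ones(3), kernel="fourier")


class TestLoocv:
    def test_perfect_linear_data_near_zero_mae(self):
        X, y, _ = _linear_data(n=20, p=2, noise=0.0, seed=13)
        cv = loocv("ols", X, y)
        assert cv.mae < 1e-8

    def test_mae_rmse_hand_arithmetic(self):
        assert mae([3.0, 4.0], [0.0, 0.0]) == pytest.approx(3.5)
        assert rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(12.5))

    def test_rmse_at_least_mae_on_random_errors(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            y = rng.standard_normal(rng.integers(2, 50))
            pred = rng.standard_normal(len(y))
            assert rmse(y, pred) >= mae(y, pred) - 1e-15

    def test_degenerate_training_fold_falls_back_to_mean(self):
        y = np.array([5.0, 5.0, 5.0, 9.0])
        X = np.arange(4.0).reshape(-1, 1)
        with pytest.warns(UserWarning, match="constant target"):
            cv = loocv("ols", X, y)
        assert cv.predictions[3] == pytest.approx(5.0)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            loocv("ols", np.zeros((2, 1)), np.ones(2))

    def test_nested_and_flat_tuning_both_run(self):
        X, y, _ = _linear_data(n=15, p=2, noise=0.5, seed=15)
        grid = default_grid("ridge")[:3]
        nested = loocv("ridge", X, y, grid=grid, inner_cv=3, nested=True, seed=1)
        flat = loocv("ridge", X, y, grid=grid, inner_cv=3, nested=False, seed=1)
        assert isinstance(nested, CVResult) and isinstance(flat, CVResult)
        assert len(set(tuple(sorted(p.items())) for p in flat.chosen_params)) == 1


class TestCompareToReference:
    def test_identical_errors_p_one_with_warning(self):
        e = np.abs(np.random.default_rng(16).standard_normal(10))
        with pytest.warns(UserWarning, match="zero"):
            assert compare_to_reference(e, e) == 1.0

    def test_uniformly_smaller_errors_highly_significant(self):
        rng = np.random.default_rng(17)
        ref = np.abs(rng.standard_normal(20)) + 1.0
        model = ref - 0.5
        assert compare_to_reference(model, ref) < 0.001

    def test_invariant_to_pair_order_permutation(self):
        rng = np.random.default_rng(18)
        a = np.abs(rng.standard_normal(30))
        b = np.abs(rng.standard_normal(30))
        perm = rng.permutation(30)
        assert compare_to_reference(a, b) == pytest.approx(compare_to_reference(a[perm], b[perm]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            compare_to_reference([1.0], [1.0, 2.0])


class TestFeatureSelection:
    def test_recovers_planted_support_on_strong_signal(self):
        rng = np.random.default_rng(19)
        n, p = 150, 20
        X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"f{j}" for j in range(p)])
        y = 2.0 * X["f1"] - 1.5 * X["f4"] + 1.0 * X["f7"] + 0.3 * rng.standard_normal(n)
        sel = select_features_lasso(X, y.to_numpy(), seed=0)
        assert {"f1", "f4", "f7"} <= set(sel.selected)

    def test_pure_noise_selects_near_empty_set(self):
        rng = np.random.default_rng(20)
        X = pd.DataFrame(rng.standard_normal((120, 15)))
        hits = []
        for seed in range(3):
            y = np.random.default_rng(100 + seed).standard_normal(120)
            sel = select_features_lasso(X, y, seed=seed)
            hits.append(len(sel.selected))
        assert np.mean(hits) <= 3

    def test_empty_selection_warns_and_falls_back(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        y = np.zeros(10)
        y[0] = 1e-9
        with pytest.warns(UserWarning, match="no features"):
            sel = select_features_lasso(X, y, seed=0)
        assert sel.selected == []


class TestPerArmFactorization:
    def test_no_cross_arm_leakage(self, encoded_small_trial):
        """Perturbing the other arm's patients must not change a fitted model."""
        X, y = encoded_small_trial
        bt = (y["arm"] == "BT").to_numpy()
        fit1 = fit_ridge(X.loc[bt], y.loc[bt, "qaly"].to_numpy(), 1.0, arm="BT", target="outcome")
        # corrupt the TAU rows entirely; BT fit must be bit-identical
        X2 = X.copy()
        X2.loc[~bt] = 1e6
        fit2 = fit_ridge(X2.loc[bt], y.loc[bt, "qaly"].to_numpy(), 1.0, arm="BT", target="outcome")
        np.testing.assert_array_equal(fit1.coefficients, fit2.coefficients)
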