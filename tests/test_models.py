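"""Loss/kernel primitives and the six regression model families."""

import numpy as np
import pytest
import statsmodels.api as sm

from chlorospec.errors import ConfigurationError, DomainError, InputError
from chlorospec.models import (
    FINE_GAUSSIAN_KERNEL_SCALE,
    GaussianKernelParams,
    HuberConfig,
    MaternParams,
    ModelSpec,
    fit_gpr,
    fit_model,
    fit_robust_linear,
    fit_stepwise,
    fit_svr,
    fit_trilayer_nn,
    huber_loss,
    kernel_gaussian,
    kernel_matern52,
    predict,
)


class TestHuberLoss:
    def test_zero_residual(self):
        assert huber_loss(0.0, 1.0) == 0.0

    def test_branch_agreement_at_knot(self):
        # both branches give delta^2/2 at |r| = delta
        quad = 0.5 * 1.0**2
        lin = 1.0 * (1.0 - 0.5 * 1.0)
        assert quad == lin == huber_loss(1.0, 1.0)

    def test_linear_branch_hand_value(self):
        assert huber_loss(3.0, 1.0) == pytest.approx(2.5, abs=1e-15)

    def test_convexity_and_continuity(self):
        r = np.linspace(-5, 5, 2001)
        loss = huber_loss(r, 1.3)
        second_diff = np.diff(loss, 2)
        assert (second_diff >= -1e-12).all()
        # one-sided derivatives match at the knot
        h = 1e-7
        left = (huber_loss(1.3, 1.3) - huber_loss(1.3 - h, 1.3)) / h
        right = (huber_loss(1.3 + h, 1.3) - huber_loss(1.3, 1.3)) / h
        assert left == pytest.approx(right, abs=1e-5)

    def test_invalid_delta_rejected(self):
        with pytest.raises(DomainError):
            huber_loss(1.0, 0.0)


class TestKernels:
    def test_gaussian_unity_at_equal_points(self):
        x = np.array([1.0, -2.0, 0.5])
        assert kernel_gaussian(x, x, GaussianKernelParams(0.7)) == 1.0

    def test_gaussian_e_inverse_at_sigma_sqrt2(self):
        sigma = 0.9
        x = np.zeros(2)
        y = np.array([sigma * np.sqrt(2.0), 0.0])
        assert kernel_gaussian(x, y, GaussianKernelParams(sigma)) == pytest.approx(
            np.exp(-1.0), abs=1e-12
        )

    def test_matern_value_at_origin_and_hand_point(self):
        params = MaternParams(sigma=1.0, length_scale=1.0)
        assert kernel_matern52(0.0, params) == 1.0
        expected = (1 + np.sqrt(5) + 5 / 3) * np.exp(-np.sqrt(5))
        assert expected == pytest.approx(0.5240, abs=5e-5)
        assert kernel_matern52(1.0, params) == pytest.approx(expected, abs=1e-12)

    def test_matern_tail_decay(self):
        assert kernel_matern52(10.0, MaternParams(1.0, 1.0)) < 1e-6

    def test_matern_monotone_decreasing(self):
        r = np.linspace(0, 5, 200)
        k = kernel_matern52(r, MaternParams(2.0, 0.8))
        assert (np.diff(k) < 0).all()

    @pytest.mark.parametrize("which", ["gaussian", "matern"])
    def test_gram_matrices_positive_semidefinite(self, which):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3))
        gram = np.empty((20, 20))
        for i in range(20):
            for j in range(20):
                if which == "gaussian":
                    gram[i, j] = kernel_gaussian(pts[i], pts[j], GaussianKernelParams(1.2))
                else:
                    r = np.linalg.norm(pts[i] - pts[j])
                    gram[i, j] = kernel_matern52(r, MaternParams(1.0, 1.5))
        gram = (gram + gram.T) / 2
        assert np.linalg.eigvalsh(gram).min() >= -1e-10

    def test_negative_distance_rejected(self):
        with pytest.raises(DomainError):
            kernel_matern52(-0.1, MaternParams(1.0, 1.0))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            kernel_gaussian(np.zeros(2), np.zeros(3), GaussianKernelParams(1.0))


class TestRobustLinear:
    def test_exact_linear_data_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        beta = np.array([2.0, -1.0, 0.5])
        model = fit_robust_linear(X, X @ beta + 4.0)
        np.testing.assert_allclose(model.state["coefficients"], beta, atol=1e-8)
        assert model.state["intercept"] == pytest.approx(4.0, abs=1e-8)

    def test_large_delta_matches_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 2))
        y = X @ [1.0, -2.0] + rng.normal(0, 1.0, 80)
        model = fit_robust_linear(X, y, HuberConfig(delta=1e9))
        design = np.column_stack([np.ones(80), X])
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        fitted = np.r_[model.state["intercept"], model.state["coefficients"]]
        np.testing.assert_allclose(fitted, ols, atol=1e-4)

    def test_outlier_downweighted_vs_ols(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 2))
        beta = np.array([3.0, -1.5])
        y = X @ beta + rng.normal(0, 0.5, 100)
        y[0] += 200.0
        robust = fit_robust_linear(X, y)
        design = np.column_stack([np.ones(100), X])
        ols = np.linalg.lstsq(design, y, rcond=None)[0][1:]
        err_rob = np.abs(np.array(robust.state["coefficients"]) - beta).max()
        err_ols = np.abs(ols - beta).max()
        assert err_rob < err_ols

    def test_matches_statsmodels_rlm(self):
        # independent IRLS implementation: statsmodels RLM with HuberT
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 3))
        y = X @ [1.0, 2.0, -1.0] + rng.standard_t(3, 120)
        mine = fit_robust_linear(X, y)
        ref = sm.RLM(y, sm.add_constant(X), M=sm.robust.norms.HuberT()).fit()
        fitted = np.r_[mine.state["intercept"], mine.state["coefficients"]]
        np.testing.assert_allclose(fitted, ref.params, rtol=2e-2, atol=2e-2)

    def test_singular_design_rejected(self):
        X = np.ones((30, 2))
        with pytest.raises(Exception):
            fit_robust_linear(X, np.arange(30.0))


class TestStepwise:
    def test_predictive_feature_selected(self):
        successes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 10))
            y = 3.0 * X[:, 0] + rng.normal(0, 1.0, 200)
            model = fit_stepwise(X, y)
            successes += any("x1" == t or t.startswith("x1*") or t.endswith("*x1")
                             for t in model.state["selected_terms"])
        assert successes >= 18

    def test_all_noise_forward_mostly_empty(self):
        empty = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(100, 10))
            y = rng.normal(size=100)
            model = fit_stepwise(X, y, direction="forward", include_interactions=False)
            empty += len(model.state["selected_terms"]) == 0
        assert empty > 50

    def test_zero_steps_returns_initial_linear_model(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        model = fit_stepwise(X, y, max_steps=0)
        assert model.state["selected_terms"] == ["x1", "x2", "x3"]

    def test_interaction_recovered(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 4))
        y = 2.0 * X[:, 0] * X[:, 1] + rng.normal(0, 0.5, 300)
        model = fit_stepwise(X, y)
        assert "x1*x2" in model.state["selected_terms"]

    def test_invalid_thresholds_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        with pytest.raises(ConfigurationError):
            fit_stepwise(X, rng.normal(size=30), p_enter=0.2, p_remove=0.1)


class TestSvr:
    def test_quadratic_kernel_capacity(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, size=(150, 2))
        y = 100.0 * (X[:, 0] + X[:, 1]) ** 2
        model = fit_svr(X, y, ModelSpec("svm_quadratic"))
        pred = predict(model, X)
        r2 = 1 - ((y - pred) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 > 0.99

    def test_fine_gaussian_stores_kernel_scale(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 2))
        model = fit_svr(X, rng.normal(size=40), ModelSpec("svm_fine_gaussian"))
        assert model.state["kernel_scale"] == FINE_GAUSSIAN_KERNEL_SCALE

    def test_huge_epsilon_gives_constant_prediction(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 2))
        y = X @ [1.0, 2.0] + rng.normal(0, 0.1, 60)
        span = y.max() - y.min()
        model = fit_svr(X, y, ModelSpec("svm_quadratic", hyperparams={"epsilon": 2 * span}))
        pred = predict(model, X)
        assert pred.std() < 1e-6
        assert np.abs(y - pred).max() <= 2 * span + 1e-9


class TestGpr:
    def test_interpolates_noise_free_training_data(self):
        x = np.linspace(0, 1, 20)
        y = np.sin(2 * np.pi * x)
        model = fit_gpr(x, y, ModelSpec("gpr_matern52", hyperparams={"noise": "zero"}))
        np.testing.assert_allclose(predict(model, x), y, atol=1e-6)

    def test_reverts_to_constant_mean_far_from_data(self):
        x = np.linspace(0, 1, 25)
        y = 5.0 + np.sin(2 * np.pi * x)
        model = fit_gpr(x, y)
        far = predict(model, np.array([1e6]))
        assert far[0] == pytest.approx(y.mean(), abs=1e-3 * max(1.0, abs(y.mean())))

    def test_heldout_rmse_below_twice_noise(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 80)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.1, 80)
        model = fit_gpr(x, y)
        xe = rng.uniform(0, 1, 300)
        rmse = np.sqrt(((predict(model, xe) - np.sin(2 * np.pi * xe)) ** 2).mean())
        assert rmse < 0.2

    def test_optimization_improves_marginal_likelihood(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 2, 40)
        y = np.cos(3 * x) + rng.normal(0, 0.05, 40)
        model = fit_gpr(x, y)
        assert np.isfinite(model.state["log_marginal_likelihood"])


class TestTrilayerNN:
    def test_linear_target_capacity(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(500, 4))
        y = 100.0 * (X @ [1.0, 2.0, -1.0, 0.5])
        model = fit_trilayer_nn(X, y, ModelSpec("trilayer_nn", seed=0))
        rmse = np.sqrt(((predict(model, X) - y) ** 2).mean())
        assert rmse < 0.01 * y.std()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(80, 3))
        y = rng.normal(size=80)
        a = fit_trilayer_nn(X, y, ModelSpec("trilayer_nn", seed=5))
        b = fit_trilayer_nn(X, y, ModelSpec("trilayer_nn", seed=5))
        assert np.array_equal(predict(a, X), predict(b, X))

    def test_iteration_limit_respected(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        model = fit_trilayer_nn(X, y, ModelSpec("trilayer_nn", hyperparams={"iteration_limit": 1}))
        assert model.training_summary["iterations"] == 1
        assert not model.training_summary["converged"]


class TestPredictContract:
    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 3))
        y = X @ [1.0, -1.0, 2.0] + rng.normal(0, 0.1, 60)
        model = fit_model(X, y, ModelSpec("gpr_matern52"))
        perm = rng.permutation(60)
        np.testing.assert_allclose(predict(model, X[perm]), predict(model, X)[perm], atol=1e-10)

    def test_single_row_prediction(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 2))
        model = fit_robust_linear(X, X @ [1.0, 1.0])
        assert predict(model, X[:1]).shape == (1,)

    def test_feature_count_mismatch_rejected(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(40, 2))
        model = fit_robust_linear(X, X @ [1.0, 1.0])
        with pytest.raises(InputError):
            predict(model, rng.normal(size=(5, 3)))

    def test_standardization_round_trip_consistency(self):
        # a standardizing model predicts identically for the same rows,
        # whether passed once or embedded in a larger batch
        rng = np.random.default_rng(15)
        X = rng.normal(size=(50, 3))
        y = X @ [2.0, 0.5, -1.0] + rng.normal(0, 0.05, 50)
        model = fit_svr(X, y, ModelSpec("svm_quadratic"))
        np.testing.assert_allclose(predict(model, X[:5]), predict(model, X)[:5], atol=1e-12)
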