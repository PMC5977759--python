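"""PLS / SPLS / elastic-net AFT fitters and cross-validated tuning."""

import numpy as np
import pytest

from aftsurv.aft_fitters import (
    CVFitter,
    CVPlan,
    cross_validate,
    cv_enet,
    fit_enet,
    fit_lasso,
    fit_ols,
    fit_pls,
    fit_spls,
    lambda_grid,
    predict_time,
    _pls1,
)


@pytest.fixture(scope="module")
def regression_instance():
    rng = np.random.default_rng(42)
    n, p = 100, 200
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:5] = 1.0
    y = 1.5 + X @ beta + 0.3 * rng.standard_normal(n)
    return X, y, beta


class TestPLS:
    def test_single_column_equals_simple_regression(self, rng):
        x = rng.standard_normal(50)[:, None]
        y = 2.0 + 0.7 * x.ravel() + 0.1 * rng.standard_normal(50)
        fit = fit_pls(x, y, v=1)
        slope = np.cov(x.ravel(), y)[0, 1] / np.var(x.ravel(), ddof=1)
        assert fit.beta[0] == pytest.approx(slope, rel=1e-10)

    def test_full_rank_factors_equal_ols(self, rng):
        n, p = 40, 5
        X = rng.standard_normal((n, p))
        y = X @ rng.standard_normal(p) + 0.2 * rng.standard_normal(n)
        fit = fit_pls(X, y, v=p)
        ols = fit_ols(X, y)
        pred_pls = predict_time(fit, X)
        pred_ols = predict_time(ols, X)
        np.testing.assert_allclose(pred_pls, pred_ols, rtol=1e-8)

    def test_latent_scores_pairwise_orthogonal(self, rng):
        X = rng.standard_normal((60, 20))
        y = rng.standard_normal(60)
        _, scores, _ = _pls1(X - X.mean(0), y - y.mean(), 5)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_matches_sklearn_pls(self, regression_instance):
        from sklearn.cross_decomposition import PLSRegression

        X, y, _ = regression_instance
        fit = fit_pls(X, y, v=3)
        sk = PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(fit.beta, sk.coef_.ravel(), atol=1e-10)

    def test_v_out_of_range_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            fit_pls(X, rng.standard_normal(10), v=10)

    def test_rank_exhaustion_reduces_v(self, rng):
        X = np.repeat(rng.standard_normal((30, 2)), [2, 1], axis=1)[:, [0, 0, 1]]
        y = X[:, 0] + 0.1 * rng.standard_normal(30)
        with pytest.warns(RuntimeWarning, match="rank"):
            fit = fit_pls(X, y, v=10)
        assert fit.tuning["v_used"] < 10


class TestSPLS:
    def test_eta_zero_reproduces_pls(self, regression_instance):
        X, y, _ = regression_instance
        a = fit_pls(X, y, v=3)
        b = fit_spls(X, y, v=3, eta=0.0)
        np.testing.assert_allclose(
            predict_time(b, X), predict_time(a, X), rtol=1e-6
        )

    def test_eta_near_one_selects_one_loading_per_step(self, rng):
        X = rng.standard_normal((50, 30))
        y = rng.standard_normal(50)
        fit = fit_spls(X, y, v=1, eta=0.99)
        assert np.count_nonzero(fit.beta) <= 1

    def test_support_recovery(self):
        """5 signal among 200 columns, n=100: >=4/5 recovered in >=80%."""
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            X = rng.standard_normal((100, 200))
            beta = np.zeros(200)
            beta[:5] = 1.0
            y = X @ beta + 0.5 * rng.standard_normal(100)
            fit = fit_spls(X, y, v=3, eta=0.8)
            sup = np.nonzero(fit.beta)[0]
            hits += np.isin(np.arange(5), sup).sum() >= 4
        assert hits >= 16

    def test_eta_validation(self, rng):
        X = rng.standard_normal((20, 5))
        with pytest.raises(ValueError):
            fit_spls(X, rng.standard_normal(20), v=2, eta=1.0)


class TestElasticNet:
    def test_huge_lambda_gives_null_model(self, regression_instance):
        X, y, _ = regression_instance
        fit = fit_enet(X, y, lam=1e9, alpha=0.5)
        assert np.count_nonzero(fit.beta) == 0
        assert fit.intercept == pytest.approx(y.mean(), rel=1e-10)

    def test_alpha_one_is_lasso(self, regression_instance):
        X, y, _ = regression_instance
        a = fit_enet(X, y, lam=5.0, alpha=1.0)
        b = fit_lasso(X, y, lam=5.0)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-6)
        assert a.method == "LASSO"

    def test_objective_against_convex_oracle(self, rng):
        """Coordinate-descent solution matches a general-purpose optimiser
        and beats random perturbations on the printed objective."""
        from scipy.optimize import minimize

        n, p = 20, 3
        X = rng.standard_normal((n, p))
        y = X @ np.array([1.0, -0.5, 0.0]) + 0.2 * rng.standard_normal(n)
        lam, alpha = 2.0, 0.7
        fit = fit_enet(X, y, lam, alpha)

        def objective(par):
            b, c = par[:p], par[p]
            r = y - c - X @ b
            return 0.5 * r @ r + lam * (
                0.5 * (1 - alpha) * b @ b + alpha * np.abs(b).sum()
            )

        res = minimize(objective, np.zeros(p + 1), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 50_000})
        np.testing.assert_allclose(fit.beta, res.x[:p], atol=1e-5)
        ours = objective(np.r_[fit.beta, fit.intercept])
        for _ in range(1000):
            pert = np.r_[fit.beta, fit.intercept] + rng.normal(0, 0.01, p + 1)
            assert objective(pert) >= ours - 1e-12

    def test_nonzero_count_weakly_monotone_in_lambda(self):
        # fixed well-conditioned instance; support growth along the path
        rng = np.random.default_rng(10)
        n, p = 60, 8
        X = rng.standard_normal((n, p))
        y = X @ np.array([2.0, -1.5, 1.0, 0.5, 0, 0, 0, 0]) \
            + 0.2 * rng.standard_normal(n)
        lams = lambda_grid(X, y, alpha=1.0, num=20)
        nnz = [np.count_nonzero(fit_lasso(X, y, lam).beta) for lam in lams]
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))  # lams decreasing

    def test_parameter_validation(self, regression_instance):
        X, y, _ = regression_instance
        with pytest.raises(ValueError):
            fit_enet(X, y, lam=-1.0, alpha=0.5)
        with pytest.raises(ValueError):
            fit_enet(X, y, lam=1.0, alpha=1.5)


class TestPredictTime:
    def test_null_beta_constant_prediction(self, rng):
        X = rng.standard_normal((30, 4))
        fit = fit_enet(X, np.full(30, 2.0), lam=1e8, alpha=1.0)
        np.testing.assert_allclose(predict_time(fit, X), np.exp(fit.intercept))

    def test_noise_free_generator_inverse(self, rng):
        X = rng.standard_normal((60, 5))
        beta = np.array([0.5, -0.3, 0.0, 0.2, 0.0])
        T = np.exp(1.0 + X @ beta)
        fit = fit_ols(X, np.log(T))
        np.testing.assert_allclose(predict_time(fit, X), T, rtol=1e-10)

    def test_monotone_in_positive_coefficient(self, rng):
        X = rng.standard_normal((40, 3))
        y = 1.0 + 0.8 * X[:, 0] + 0.1 * rng.standard_normal(40)
        fit = fit_ols(X, y)
        assert fit.beta[0] > 0
        base = X.copy()
        bumped = X.copy()
        bumped[:, 0] += 1.0
        assert np.all(predict_time(fit, bumped) > predict_time(fit, base))

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.standard_normal((20, 4))
        fit = fit_ols(X, rng.standard_normal(20))
        with pytest.raises(ValueError, match="columns"):
            predict_time(fit, X[:, :2])


class TestCrossValidation:
    def test_single_point_grid_returned(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        best, curve = cross_validate(fit_pls, X, y, [{"v": 2}], CVPlan(seed=1))
        assert best == {"v": 2}
        assert len(curve) == 1

    def test_folds_partition_and_balance(self):
        folds = CVPlan(n_folds=10, seed=3).folds(95)
        lengths = [len(f) for f in folds]
        assert sum(lengths) == 95
        assert max(lengths) - min(lengths) <= 1
        assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(95))

    def test_two_factor_data_selects_small_v(self):
        """PLS CV picks v in {2,3} for data driven by 2 latent factors."""
        ok = 0
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            n, p = 80, 40
            F = rng.standard_normal((n, 2))
            X = F @ rng.standard_normal((2, p)) + 0.3 * rng.standard_normal((n, p))
            y = F @ np.array([1.5, -1.0]) + 0.3 * rng.standard_normal(n)
            best, _ = cross_validate(
                fit_pls, X, y, [{"v": v} for v in range(1, 11)], CVPlan(seed=s)
            )
            ok += best["v"] in (2, 3)
        assert ok >= 16

    def test_pure_noise_selection_not_worse_than_one_se(self, rng):
        X = rng.standard_normal((60, 10))
        y = rng.standard_normal(60)
        best, curve = cross_validate(
            fit_pls, X, y, [{"v": v} for v in range(1, 6)], CVPlan(seed=2)
        )
        mses = np.array([c["cv_mse"] for c in curve])
        best_mse = next(c["cv_mse"] for c in curve if c["v"] == best["v"])
        se = mses.std(ddof=1)
        assert best_mse <= mses.min() + se

    def test_cv_enet_agrees_with_generic_cv(self, rng):
        X = rng.standard_normal((50, 8))
        y = X[:, 0] - 0.5 * X[:, 1] + 0.3 * rng.standard_normal(50)
        lams = lambda_grid(X, y, 1.0, num=10)
        plan = CVPlan(seed=7)
        best_fast, curve_fast = cv_enet(X, y, [1.0], lams, plan)
        grid = [{"lam": float(l), "alpha": 1.0} for l in lams]
        best_gen, curve_gen = cross_validate(
            lambda Xs, ys, lam, alpha: fit_enet(Xs, ys, lam, alpha),
            X, y, [{"lam": float(l), "alpha": 1.0} for l in lams], plan,
        )
        fast = {round(c["lambda"], 8): c["cv_mse"] for c in curve_fast}
        gen = {round(c["lam"], 8): c["cv_mse"] for c in curve_gen}
        for k in gen:
            assert fast[k] == pytest.approx(gen[k], rel=1e-4)

    def test_cvfitter_deterministic(self, rng):
        X = rng.standard_normal((50, 12))
        y = X[:, 0] + 0.2 * rng.standard_normal(50)
        fits = [CVFitter("LASSO", cv_seed=3).fit(X, y) for _ in range(2)]
        np.testing.assert_array_equal(fits[0].beta, fits[1].beta)

    def test_cvfitter_freeze_after_first(self, rng):
        X = rng.standard_normal((50, 12))
        y = X[:, 0] + 0.2 * rng.standard_normal(50)
        f = CVFitter("LASSO", retune="first", cv_seed=3)
        f.fit(X, y)
        frozen = dict(f.tuning)
        f.fit(X[:40], y[:40])  # different data must not re-tune
        assert f.tuning == frozen
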