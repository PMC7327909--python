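import numpy as np
import pandas as pd
import pytest

from spitzsig import (
    cv_deviance,
    generate_cohort,
    lasso_logistic_path,
    normalize_voom,
    score_samples,
    stability_select,
    SyntheticConfig,
)
from spitzsig.exceptions import ParameterError
from spitzsig.signature import SignatureModel, _rep_seed, binomial_deviance


def newton_logistic(X, y, tol=1e-12, max_iter=200):
    """Independent unpenalized logistic MLE via Newton-Raphson."""
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    for _ in range(max_iter):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = Z.T @ (y - mu)
        hess = (Z * W[:, None]).T @ Z
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestLassoPath:
    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 20))
        y = (rng.random(30) < 0.5).astype(float)
        fit = lasso_logistic_path(X, y)
        assert np.all(fit.coef_path[:, 0] == 0.0)
        assert np.any(fit.coef_path[:, 1:] != 0.0)

    def test_orthonormal_gaussian_soft_threshold(self):
        # squared-loss check mode on an orthonormal design: the solution is
        # the soft-thresholded univariate estimate sign(b) * max(|b|-lam, 0)
        n = 12
        rng = np.random.default_rng(1)
        a = rng.normal(size=(n, 2))
        a -= a.mean(axis=0)  # zero-mean columns -> QR stays zero-mean
        q, _ = np.linalg.qr(a)
        X = q * np.sqrt(n)  # zero mean, unit population sd, (1/n) X'X = I
        y = 1.5 * X[:, 0] - 0.7 * X[:, 1] + rng.normal(0, 0.1, n)
        y = y - y.mean()
        b = X.T @ y / n  # univariate OLS estimates
        fit = lasso_logistic_path(X, y, family="gaussian", n_lambda=40)
        for li, lam in enumerate(fit.lambda_path):
            expected = np.sign(b) * np.maximum(np.abs(b) - lam, 0.0)
            np.testing.assert_allclose(fit.coef_path[:, li], expected, atol=1e-6)

    def test_tiny_lambda_matches_newton_mle(self):
        rng = np.random.default_rng(5)
        n, p = 200, 3
        X = rng.normal(size=(n, p))
        beta_true = np.array([0.8, -0.5, 0.2])
        prob = 1 / (1 + np.exp(-(0.3 + X @ beta_true)))
        y = (rng.random(n) < prob).astype(float)
        fit = lasso_logistic_path(X, y, n_lambda=60, lambda_min_ratio=1e-5)
        ref = newton_logistic(X, y)
        np.testing.assert_allclose(fit.intercept_path[-1], ref[0], atol=1e-3)
        np.testing.assert_allclose(fit.coef_path[:, -1], ref[1:], atol=1e-3)

    def test_debug_mode_agrees_with_fast_kernel(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 15))
        y = (rng.random(25) < 0.5).astype(float)
        y[:5] = 1.0  # ensure both classes
        fast = lasso_logistic_path(X, y, n_lambda=30)
        slow = lasso_logistic_path(X, y, n_lambda=30, debug=True)
        np.testing.assert_allclose(fast.coef_path, slow.coef_path, atol=1e-5)

    def test_path_continuity_under_grid_refinement(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 10))
        beta_true = np.zeros(10)
        beta_true[:2] = [1.5, -1.0]
        y = (rng.random(40) < 1 / (1 + np.exp(-(X @ beta_true)))).astype(float)
        coarse = lasso_logistic_path(X, y, n_lambda=100)
        fine = lasso_logistic_path(X, y, n_lambda=1000)
        step_coarse = np.abs(np.diff(coarse.coef_path, axis=1)).max()
        step_fine = np.abs(np.diff(fine.coef_path, axis=1)).max()
        assert step_fine < step_coarse / 2

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ParameterError):
            lasso_logistic_path(X, np.ones(10))

    def test_constant_column_gets_zero_weight(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        X[:, 2] = 7.0
        y = (rng.random(30) < 0.5).astype(float)
        y[:5], y[-5:] = 0.0, 1.0
        fit = lasso_logistic_path(X, y)
        assert np.all(fit.coef_path[2] == 0.0)


class TestCvDeviance:
    def _data(self, seed=0, informative=True, n=80):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 12))
        if informative:
            y = (rng.random(n) < 1 / (1 + np.exp(-3 * X[:, 0]))).astype(float)
        else:
            y = (np.arange(n) % 2).astype(float)
            rng.shuffle(y)
        return X, y

    def test_same_seed_identical(self):
        X, y = self._data()
        fit = lasso_logistic_path(X, y)
        a = cv_deviance(X, y, fit, seed=9)
        b = cv_deviance(X, y, fit, seed=9)
        np.testing.assert_array_equal(a.cv_dev, b.cv_dev)
        assert a.lambda_star == b.lambda_star

    def test_informative_gene_enters_selected_model(self):
        X, y = self._data(informative=True)
        fit = lasso_logistic_path(X, y)
        cv = cv_deviance(X, y, fit, seed=1)
        assert fit.coef_path[0, cv.lambda_star_index] != 0.0

    def test_noise_selects_near_null_end(self):
        hits = []
        for seed in range(5):
            X, y = self._data(seed=seed, informative=False)
            fit = lasso_logistic_path(X, y)
            cv = cv_deviance(X, y, fit, seed=seed)
            nz = int((fit.coef_path[:, cv.lambda_star_index] != 0).sum())
            hits.append(nz)
        assert np.median(hits) <= 2

    def test_deviance_positive_finite(self):
        X, y = self._data()
        fit = lasso_logistic_path(X, y)
        cv = cv_deviance(X, y, fit, seed=2)
        assert np.all(np.isfinite(cv.cv_dev)) and np.all(cv.cv_dev > 0)

    def test_binomial_deviance_formula(self):
        y = np.array([1.0, 0.0])
        p = np.array([0.8, 0.3])
        expected = -2 * np.mean([np.log(0.8), np.log(0.7)])
        assert binomial_deviance(y, p) == pytest.approx(expected)


class TestStabilitySelect:
    def test_reps_below_threshold_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 5))
        y = np.array([0.0] * 10 + [1.0] * 10)
        with pytest.raises(ParameterError):
            stability_select(X, y, n_reps=10, threshold=20)

    def test_rep_seeds_are_distinct_and_reproducible(self):
        s = [_rep_seed(7, r) for r in range(100)]
        assert len(set(s)) == 100
        assert s == [_rep_seed(7, r) for r in range(100)]

    def test_planted_signature_recovered_small(self):
        cfg = SyntheticConfig(
            n_per_group=(15, 0, 12),
            n_genes=120,
            n_housekeeping=10,
            n_de_genes=0,
            n_signature_genes=4,
            signature_step=1.2,
            seed=13,
        )
        cohort = generate_cohort(cfg)
        expr = normalize_voom(cohort)
        mask = cohort.group.isin(["SN", "MST"]).to_numpy()
        X = expr.logexp.to_numpy().T[mask]
        y = (cohort.group[mask] == "MST").to_numpy(float)
        model = stability_select(
            X, y, n_reps=40, threshold=20, seed=3,
            feature_names=list(expr.logexp.index),
        )
        planted = set(cohort.gene_truth.index[cohort.gene_truth.is_signature])
        selected = set(model.signature_genes)
        assert len(selected & planted) >= 3
        assert len(selected - planted) <= 2

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 25))
        X[:, 3] += 2.0 * np.repeat([0, 1], 15)
        y = np.repeat([0.0, 1.0], 15)
        names = [f"g{j}" for j in range(25)]
        a = stability_select(X, y, n_reps=10, threshold=5, seed=2, feature_names=names)
        perm = rng.permutation(25)
        b = stability_select(
            X[:, perm], y, n_reps=10, threshold=5, seed=2,
            feature_names=[names[j] for j in perm],
        )
        pd.testing.assert_series_equal(
            a.stats["selection_count"].sort_index(),
            b.stats["selection_count"].sort_index(),
        )
        np.testing.assert_allclose(
            a.stats["mean_coef"].sort_index(),
            b.stats["mean_coef"].sort_index(),
            atol=1e-6,
        )

    def test_mean_coef_includes_zero_reps(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 8))
        X[:, 0] += 3.0 * np.repeat([0, 1], 15)
        y = np.repeat([0.0, 1.0], 15)
        full = stability_select(X, y, n_reps=20, threshold=10, seed=1)
        sel_only = stability_select(
            X, y, n_reps=20, threshold=10, seed=1, average_selected_only=True
        )
        cnt = full.stats["selection_count"]
        partial = cnt[(cnt > 0) & (cnt < 20)]
        if len(partial):
            g = partial.index[0]
            assert abs(full.stats.loc[g, "mean_coef"]) < abs(
                sel_only.stats.loc[g, "mean_coef"]
            )


class TestScoreSamples:
    def _model(self, weights: dict[str, float]) -> SignatureModel:
        stats = pd.DataFrame(
            {
                "selection_count": [500] * len(weights),
                "mean_coef": list(weights.values()),
            },
            index=list(weights.keys()),
        )
        return SignatureModel(stats=stats, n_reps=500, selection_threshold=250)

    def test_published_weights_on_unit_expression(self):
        # six weights applied to unit expression: the raw score is their sum
        # (1.69 - 0.08 - 1.11 - 0.58 + 0.03 + 0.017 = -0.033)
        weights = {
            "NRAS": 1.69,
            "EIF2B4": -0.08,
            "NF1": -1.11,
            "BMP2": -0.58,
            "FZD9": 0.03,
            "IFNA17": 0.017,
        }
        model = self._model(weights)
        from spitzsig import CountCohort, WeightedExpression

        genes = list(weights)
        samples = ["a", "b"]
        logexp = pd.DataFrame(1.0, index=genes, columns=samples)
        logexp["b"] = 2.0  # second sample so min-max is defined
        expr = WeightedExpression(
            logexp=logexp,
            weights=pd.DataFrame(1.0, index=genes, columns=samples),
            trend=lambda x: np.ones_like(x),
        )
        cohort = CountCohort(
            counts=pd.DataFrame(1, index=genes, columns=samples),
            group=pd.Series(["SN", "MST"], index=samples),
            gene_role=pd.Series("endogenous", index=genes),
        )
        scores = score_samples(model, expr, cohort)
        assert scores.table.loc["a", "raw_score"] == pytest.approx(
            sum(weights.values()), abs=1e-12
        )
        assert sum(weights.values()) == pytest.approx(-0.033, abs=1e-12)

    def test_minmax_endpoints_and_rank_invariance(self, small_cohort, small_expr):
        genes = list(small_expr.logexp.index[:3])
        model = self._model({genes[0]: 1.0, genes[1]: -0.5, genes[2]: 0.25})
        scores = score_samples(model, small_expr, small_cohort)
        t = scores.table
        assert t["score01"].min() == 0.0 and t["score01"].max() == 1.0
        order_raw = t["raw_score"].rank(method="first")
        order_01 = t["score01"].rank(method="first")
        pd.testing.assert_series_equal(order_raw, order_01, check_names=False)

    def test_boundary_is_low(self):
        model = self._model({"g": 1.0})
        from spitzsig import CountCohort, WeightedExpression

        # raw scores 0, 0.4, 1.0 -> score01 exactly 0.4 for the middle sample
        logexp = pd.DataFrame([[0.0, 0.4, 1.0]], index=["g"], columns=["a", "b", "c"])
        expr = WeightedExpression(
            logexp=logexp,
            weights=pd.DataFrame(1.0, index=["g"], columns=["a", "b", "c"]),
            trend=lambda x: np.ones_like(x),
        )
        cohort = CountCohort(
            counts=pd.DataFrame(1, index=["g"], columns=["a", "b", "c"]),
            group=pd.Series(["SN", "AST", "MST"], index=["a", "b", "c"]),
            gene_role=pd.Series("endogenous", index=["g"]),
        )
        scores = score_samples(model, expr, cohort)
        assert scores.table.loc["b", "score01"] == pytest.approx(0.4)
        assert scores.table.loc["b", "call"] == "low"
        assert scores.table.loc["c", "call"] == "high"

    def test_missing_gene_named(self, small_cohort, small_expr):
        model = self._model({"NOT_A_GENE": 1.0})
        with pytest.raises(ParameterError, match="NOT_A_GENE"):
            score_samples(model, small_expr, small_cohort)

    def test_ast_mean_between_sn_and_mst(self, small_cohort, small_expr):
        mask = small_cohort.group.isin(["SN", "MST"]).to_numpy()
        X = small_expr.logexp.to_numpy().T[mask]
        y = (small_cohort.group[mask] == "MST").to_numpy(float)
        model = stability_select(
            X, y, n_reps=30, threshold=15, seed=5,
            feature_names=list(small_expr.logexp.index),
        )
        scores = score_samples(model, small_expr, small_cohort)
        means = scores.table.groupby("group")["score01"].mean()
        assert means["SN"] < means["AST"] < means["MST"]
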