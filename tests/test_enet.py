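"""Elastic-net wrapper: penalty limits, LOO tuning, imbalance, metrics."""

import numpy as np
import pandas as pd
import pytest

from lipidsel import enet


def ista_lasso(X, y, lam, max_iter=200_000, tol=1e-12):
    """Independent proximal-gradient oracle for
    argmin ||y - X b||^2 + lam ||b||_1 (no intercept)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    L = 2.0 * np.linalg.norm(X, 2) ** 2  # Lipschitz constant of the gradient
    b = np.zeros(X.shape[1])
    for _ in range(max_iter):
        grad = -2.0 * X.T @ (y - X @ b)
        z = b - grad / L
        b_new = np.sign(z) * np.maximum(np.abs(z) - lam / L, 0.0)
        if np.max(np.abs(b_new - b)) < tol:
            b = b_new
            break
        b = b_new
    return b


def make_frame(X):
    X = np.asarray(X, float)
    return pd.DataFrame(
        X,
        index=[f"s{i}" for i in range(X.shape[0])],
        columns=[f"f{j}" for j in range(X.shape[1])],
    )


def separable_classes(n_per_class=20, n_features=100, n_informative=10, delta=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, n_features))
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    X[n_per_class:, :n_informative] += delta
    return make_frame(X), y


class TestPenaltyLimits:
    def test_huge_lambda_zeroes_coefficients(self):
        X, y = separable_classes(10, 20, 5, seed=1)
        # drop four "b" samples so every LOO training fold shares a majority
        keep = list(range(16))
        X, y = X.iloc[keep], y[keep]
        config = enet.EnetConfig(alpha=0.5, lambda_grid=[1e6], family="binomial")
        result = enet.train_enet(X, y, config)
        assert result.n_nonzero() == 0
        # predictions collapse to the majority class
        assert set(result.loo_predictions["predicted"]) == {"a"}

    def test_ridge_closed_form_at_alpha_zero(self, rng):
        # gaussian family, no intercept/standardization:
        # b = (X'X + (lam/2) I)^-1 X'y
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        lam = 3.7
        config = enet.EnetConfig(
            alpha=0.0,
            lambda_grid=[lam],
            family="gaussian",
            standardize_inputs=False,
            fit_intercept=False,
        )
        result = enet.train_enet(make_frame(X), y, config)
        expected = np.linalg.solve(X.T @ X + (lam / 2.0) * np.eye(5), X.T @ y)
        assert np.allclose(result.coefficients.to_numpy()[0], expected, atol=1e-6)

    def test_pure_l1_matches_proximal_gradient_oracle(self, rng):
        for seed in range(3):
            local = np.random.default_rng(seed)
            X = local.normal(size=(10, 5))
            y = local.normal(size=10)
            lam = 1.5
            config = enet.EnetConfig(
                alpha=1.0,
                lambda_grid=[lam],
                family="gaussian",
                standardize_inputs=False,
                fit_intercept=False,
            )
            result = enet.train_enet(make_frame(X), y, config)
            oracle = ista_lasso(X, y, lam)
            assert np.allclose(result.coefficients.to_numpy()[0], oracle, atol=1e-5)

    def test_sparsity_monotone_along_lambda_grid(self, rng):
        X = rng.normal(size=(20, 10))
        y = X @ rng.normal(size=10) + 0.1 * rng.normal(size=20)
        grid = np.logspace(-2, 3, 10)
        nnz = []
        for lam in grid:
            config = enet.EnetConfig(
                alpha=0.5,
                lambda_grid=[lam],
                family="gaussian",
                standardize_inputs=False,
            )
            result = enet.train_enet(make_frame(X), y, config)
            nnz.append(result.n_nonzero())
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))


class TestTrainEnet:
    def test_well_separated_classes_high_loo_accuracy(self):
        accuracies = []
        for seed in range(10):
            X, y = separable_classes(20, 100, 10, delta=3.0, seed=seed)
            config = enet.EnetConfig(
                alpha=0.5, lambda_grid=np.logspace(-1, 1, 4), seed=seed
            )
            result = enet.train_enet(X, y, config)
            accuracies.append(result.accuracy)
        assert np.mean(accuracies) >= 0.95

    def test_planted_features_dominate_importance(self):
        hits = []
        for seed in range(10):
            X, y = separable_classes(20, 50, 10, delta=3.0, seed=100 + seed)
            config = enet.EnetConfig(alpha=0.5, lambda_grid=[1.0, 10.0], seed=seed)
            result = enet.train_enet(X, y, config)
            top10 = set(result.importance.head(10).index)
            planted = {f"f{j}" for j in range(10)}
            hits.append(len(top10 & planted) / 10)
        assert np.mean(hits) >= 0.8

    def test_single_sample_class_rejected(self):
        X = make_frame(np.random.default_rng(0).normal(size=(5, 3)))
        y = ["a", "a", "a", "a", "b"]
        with pytest.raises(ValueError, match="single sample"):
            enet.train_enet(X, y, enet.EnetConfig(lambda_grid=[1.0]))

    def test_non_finite_input_rejected(self):
        X = make_frame(np.full((6, 2), np.nan))
        with pytest.raises(ValueError, match="non-finite"):
            enet.train_enet(X, ["a", "b", "a", "b", "a", "b"], enet.EnetConfig())

    def test_deterministic_given_seed(self):
        X, y = separable_classes(8, 10, 3, seed=5)
        config = enet.EnetConfig(lambda_grid=[0.5, 5.0], imbalance="smote", seed=9)
        a = enet.train_enet(X, y, config)
        b = enet.train_enet(X, y, config)
        assert np.allclose(a.coefficients.to_numpy(), b.coefficients.to_numpy())
        assert a.accuracy == b.accuracy


class TestImbalanceHandling:
    @staticmethod
    def imbalanced_problem(seed, delta=1.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(48, 30))
        y = np.array(["major"] * 36 + ["minor"] * 12)
        X[36:, :5] += delta
        return make_frame(X), y

    def test_minority_recall_improves(self):
        # both class weights and SMOTE must beat no handling on 36-vs-12
        recalls = {"none": [], "class_weights": [], "smote": []}
        for seed in range(10):
            X, y = self.imbalanced_problem(seed)
            for mode in recalls:
                config = enet.EnetConfig(
                    alpha=0.5, lambda_grid=[0.3, 3.0], imbalance=mode, seed=seed
                )
                result = enet.train_enet(X, y, config)
                pred = result.loo_predictions
                minor = pred[pred["true"] == "minor"]
                recalls[mode].append((minor["predicted"] == "minor").mean())
        assert np.mean(recalls["class_weights"]) > np.mean(recalls["none"])
        assert np.mean(recalls["smote"]) > np.mean(recalls["none"])

    def test_smote_upsamples_to_majority(self, rng):
        X = rng.normal(size=(48, 4))
        y = np.array(["a"] * 36 + ["b"] * 12)
        X_out, y_out = enet.smote_oversample(X, y, k=5, seed=0)
        values, counts = np.unique(y_out, return_counts=True)
        assert dict(zip(values, counts)) == {"a": 36, "b": 36}

    def test_smote_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array(["a"] * 5 + ["b"] * 5)
        X_out, y_out = enet.smote_oversample(X, y, seed=1)
        assert X_out.shape == X.shape
        assert (X_out == X).all()

    def test_smote_points_are_convex_combinations(self, rng):
        # every synthetic point must lie on a segment between two real
        # minority points (checked exhaustively on a 12-point class)
        X = rng.normal(size=(48, 3))
        y = np.array(["a"] * 36 + ["b"] * 12)
        X_out, y_out = enet.smote_oversample(X, y, k=5, seed=2)
        minority = X[36:]
        synthetic = X_out[48:]
        assert (y_out[48:] == "b").all()
        for point in synthetic:
            found = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    seg = minority[j] - minority[i]
                    denominator = seg @ seg
                    t = (point - minority[i]) @ seg / denominator
                    if -1e-9 <= t <= 1 + 1e-9 and np.allclose(
                        minority[i] + t * seg, point, atol=1e-9
                    ):
                        found = True
                        break
                if found:
                    break
            assert found

    def test_smote_singleton_minority_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array(["a"] * 4 + ["b"])
        with pytest.raises(ValueError, match="single sample"):
            enet.smote_oversample(X, y)

    def test_smote_k_clipped_to_class_size(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array(["a"] * 7 + ["b"] * 3)
        X_out, y_out = enet.smote_oversample(X, y, k=5, seed=3)
        assert (y_out == "b").sum() == 7

    def test_holdout_never_reaches_smote_fold(self, rng):
        # structural check: the fold builder excludes the test row before
        # SMOTE, so no synthetic point can involve the held-out sample
        X = rng.normal(size=(12, 2))
        # put the holdout far away: any interpolation using it would show
        X[0] = 1e6
        y = np.array(["a"] * 8 + ["b"] * 4)
        config = enet.EnetConfig(imbalance="smote", smote_k=2, seed=0)
        X_tr, y_tr, _, _ = enet._prepare_fold(X, y, 0, config, fold_seed=1)
        # holdout removed: 7 "a" remain, "b" upsampled to match
        assert sorted(np.unique(y_tr, return_counts=True)[1]) == [7, 7]
        assert np.abs(X_tr).max() < 1e5


class TestImportanceScores:
    def _result_with_coefficients(self, coef, classes):
        return enet.EnetResult(
            coefficients=pd.DataFrame(
                coef, index=classes, columns=[f"f{j}" for j in range(np.shape(coef)[1])]
            ),
            intercepts=np.zeros(len(classes)),
            selected_lambda=1.0,
            selected_alpha=0.5,
            classes=classes,
        )

    def test_overall_is_sum_of_class_scores_and_max_100(self):
        coef = np.array(
            [[2.0, 0.0, 0.4], [0.0, 0.0, 0.1], [-1.0, 0.0, 0.0], [0.0, 0.5, 0.0]]
        )
        result = self._result_with_coefficients(coef, ["c1", "c2", "c3", "c4"])
        table = enet.importance_scores(result)
        class_cols = ["c1", "c2", "c3", "c4"]
        assert np.allclose(table[class_cols].sum(axis=1), table["Overall"])
        assert np.isclose(table["Overall"].max(), 100.0)
        assert table.loc["f1", "Overall"] < table.loc["f0", "Overall"]

    def test_published_additive_structure(self):
        # two per-class scores of one feature summing to its overall score,
        # e.g. 30.66 + 7.66 = 38.32 with another feature pinned at 100
        coef = np.array([[1.0, 0.3066], [0.0, 0.0766], [0.0, 0.0], [0.0, 0.0]])
        result = self._result_with_coefficients(coef, ["w", "x", "y", "z"])
        table = enet.importance_scores(result)
        assert np.isclose(table.loc["f0", "Overall"], 100.0)
        assert np.isclose(table.loc["f1", "w"], 30.66)
        assert np.isclose(table.loc["f1", "x"], 7.66)
        assert np.isclose(table.loc["f1", "Overall"], 38.32)

    def test_single_nonzero_scores_100(self):
        coef = np.array([[0.0, -0.7, 0.0]])
        result = self._result_with_coefficients(coef, ["pos"])
        table = enet.importance_scores(result)
        assert np.isclose(table.loc["f1", "Overall"], 100.0)
        assert np.allclose(table.drop(index="f1")["Overall"], 0.0)

    def test_scale_invariance(self):
        coef = np.array([[0.5, 1.5, 0.0]])
        a = enet.importance_scores(self._result_with_coefficients(coef, ["c"]))
        b = enet.importance_scores(self._result_with_coefficients(2 * coef, ["c"]))
        pd.testing.assert_frame_equal(a, b)

    def test_all_zero_model_warns(self):
        result = self._result_with_coefficients(np.zeros((2, 3)), ["a", "b"])
        with pytest.warns(UserWarning, match="zero"):
            table = enet.importance_scores(result)
        assert (table["Overall"] == 0).all()


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = ["a", "b", "a", "b", "a", "b"]
        metrics = enet.classification_metrics(y, y)
        assert metrics["accuracy"] == 1.0
        assert metrics["kappa_unweighted"] == 1.0
        assert metrics["kappa_weighted"] == 1.0

    def test_hand_computed_kappa(self):
        # confusion ((40, 10), (20, 30)): accuracy 0.7, p_e = 0.5, kappa 0.4
        y_true = ["a"] * 50 + ["b"] * 50
        y_pred = ["a"] * 40 + ["b"] * 10 + ["a"] * 20 + ["b"] * 30
        metrics = enet.classification_metrics(y_true, y_pred)
        assert np.isclose(metrics["accuracy"], 0.7)
        assert np.isclose(metrics["kappa_unweighted"], 0.4, atol=1e-12)
        assert metrics["confusion"].to_numpy().tolist() == [[40, 10], [20, 30]]

    def test_independent_predictions_null_kappa(self, rng):
        y_true = rng.choice(["a", "b", "c"], size=10_000)
        y_pred = rng.choice(["a", "b", "c"], size=10_000)
        metrics = enet.classification_metrics(y_true, y_pred)
        assert abs(metrics["kappa_unweighted"]) < 0.03

    def test_weighted_kappa_forgives_near_misses(self):
        stages = ["control", "non-lesional", "established", "advanced"]
        y_true = np.repeat(stages, 10)
        # off-by-one errors only
        y_pred = np.array(y_true, dtype=object)
        y_pred[::5] = [
            stages[min(stages.index(s) + 1, 3)] for s in y_true[::5]
        ]
        metrics = enet.classification_metrics(y_true, y_pred, classes=stages)
        assert metrics["kappa_weighted"] > metrics["kappa_unweighted"]

    def test_ci_is_clopper_pearson(self):
        from scipy import stats

        metrics = enet.classification_metrics(
            ["a"] * 80 + ["b"] * 20, ["a"] * 100
        )
        lo, hi = metrics["accuracy_ci"]
        assert np.isclose(lo, stats.beta.ppf(0.025, 80, 21), atol=1e-9)
        assert np.isclose(hi, stats.beta.ppf(0.975, 81, 20), atol=1e-9)
        assert lo <= metrics["accuracy"] <= hi

    def test_single_class_truth_kappa_nan(self):
        with pytest.warns(UserWarning, match="kappa"):
            metrics = enet.classification_metrics(["a", "a"], ["a", "b"])
        assert np.isnan(metrics["kappa_unweighted"])
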