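"""Tier-2 wrapper: elastic-net classification with leave-one-out tuning.

The pre-selected features (log-ratio ions or per-category CPC scores) feed
a penalized regression

    argmin_beta  loss(y, X beta) + lambda * ((1 - alpha) ||beta||_2^2 / 2
                                             + alpha ||beta||_1)

so alpha = 1 is the pure LASSO and alpha = 0 pure ridge.  For
classification the loss is the binomial / multinomial deviance, which
yields class probabilities; a gaussian (least-squares) family is kept for
closed-form cross-checks.  Lambda (and optionally alpha) is chosen to
minimize the mean leave-one-out deviance; class imbalance is handled inside
each training fold by inverse-frequency class weights or SMOTE
oversampling.  Features are ranked by the absolute value of their nonzero
coefficients, scaled so the largest overall score is 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Lasso, LogisticRegression, Ridge
from sklearn.metrics import cohen_kappa_score, confusion_matrix
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.proportion import proportion_confint

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2, 2, 9))


@dataclass
class EnetConfig:
    """Settings for :func:`train_enet`.

    alpha: L1/L2 mixing in [0, 1] (1 = LASSO); a sequence is searched by
    LOO deviance alongside the lambda grid.  lambda_grid: positive penalty
    strengths.  family: "binomial", "multinomial" or "gaussian" (the last
    for closed-form checks).  imbalance: "none", "class_weights" or
    "smote", applied inside each training fold only.  standardize_inputs:
    center/scale features on each training fold (coefficients are reported
    on the standardized scale so |beta| ranks features fairly).
    """

    alpha: float | Sequence[float] = 0.5
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
    family: str = "binomial"
    imbalance: str = "none"
    smote_k: int = 5
    seed: int = 0
    standardize_inputs: bool = True
    fit_intercept: bool = True
    max_iter: int = 5000
    tol: float = 1e-4
    kappa_weights: str = "linear"

    def __post_init__(self) -> None:
        alphas = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if np.any((alphas < 0) | (alphas > 1)):
            raise ValueError("alpha must lie in [0, 1]")
        lams = np.asarray(list(self.lambda_grid), dtype=float)
        if lams.size == 0 or np.any(lams <= 0):
            raise ValueError("lambda_grid must be nonempty and positive")
        if self.family not in ("binomial", "multinomial", "gaussian"):
            raise ValueError("family must be binomial, multinomial or gaussian")
        if self.imbalance not in ("none", "class_weights", "smote"):
            raise ValueError("imbalance must be none, class_weights or smote")

    @property
    def alphas(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.alpha, dtype=float))

    @property
    def lambdas(self) -> np.ndarray:
        return np.asarray(list(self.lambda_grid), dtype=float)


@dataclass
class EnetResult:
    """Fitted coefficients, LOO predictions, importance and metrics."""

    coefficients: pd.DataFrame  # classes x features (1 row for binary/gaussian)
    intercepts: np.ndarray
    selected_lambda: float
    selected_alpha: float
    classes: list
    loo_predictions: pd.DataFrame | None = None
    importance: pd.DataFrame | None = None
    confusion: pd.DataFrame | None = None
    accuracy: float = float("nan")
    accuracy_ci: tuple[float, float] = (float("nan"), float("nan"))
    kappa_unweighted: float = float("nan")
    kappa_weighted: float = float("nan")
    deviance_path: pd.DataFrame | None = None

    def n_nonzero(self) -> int:
        return int((np.abs(self.coefficients.to_numpy()) > 1e-10).any(axis=0).sum())


def smote_oversample(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling up to the majority class count.

    Each synthetic point lies on the segment between a minority point and
    one of its k nearest minority neighbors (uniform interpolation weight).
    If the minority class has <= k members, k is clipped to size - 1.
    Deterministic given ``seed``.  Already-balanced input is returned
    unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    if (counts == majority).all():
        return X, y
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [X], [y]
    for cls, count in zip(classes, counts):
        need = majority - count
        if need == 0:
            continue
        if count < 2:
            raise ValueError(
                f"class {cls!r} has a single sample; cannot interpolate"
            )
        members = X[y == cls]
        k_eff = min(k, count - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(members)
        _, neighbor_idx = nn.kneighbors(members)  # column 0 is the point itself
        base = rng.integers(0, count, size=need)
        pick = rng.integers(1, k_eff + 1, size=need)
        gamma = rng.uniform(0.0, 1.0, size=need)
        partners = neighbor_idx[base, pick]
        synthetic = members[base] + gamma[:, None] * (members[partners] - members[base])
        X_parts.append(synthetic)
        y_parts.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(X_parts), np.concatenate(y_parts)


def _fit_classifier(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    config: EnetConfig,
    classes: np.ndarray,
) -> LogisticRegression:
    """One penalized logistic fit under the Eq.-style penalty convention.

    scikit-learn minimizes penalty + C * sum(deviance contributions), so
    C = 1 / lambda maps the grid onto the stated objective.
    """
    if alpha == 0.0:
        penalty, l1_ratio = "l2", None
    elif alpha == 1.0:
        penalty, l1_ratio = "l1", None
    else:
        penalty, l1_ratio = "elasticnet", alpha
    class_weight = "balanced" if config.imbalance == "class_weights" else None
    model = LogisticRegression(
        penalty=penalty,
        l1_ratio=l1_ratio,
        C=1.0 / lam,
        solver="saga",
        max_iter=config.max_iter,
        tol=config.tol,
        fit_intercept=config.fit_intercept,
        class_weight=class_weight,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def _fit_gaussian(
    X: np.ndarray, y: np.ndarray, alpha: float, lam: float, config: EnetConfig
):
    """Least-squares elastic net under ||y - X b||^2 + lam*((1-a)||b||^2/2 + a||b||_1).

    Mapping to scikit-learn's (1/2n)||.||^2 objective gives
    sklearn_alpha = lam / (2n); ridge (alpha = 0) uses its closed form with
    penalty matrix (lam / 2) I.
    """
    n = X.shape[0]
    if alpha == 0.0:
        model = Ridge(alpha=lam / 2.0, fit_intercept=config.fit_intercept)
    elif alpha == 1.0:
        model = Lasso(
            alpha=lam / (2.0 * n),
            fit_intercept=config.fit_intercept,
            max_iter=200_000,
            tol=1e-10,
        )
    else:
        model = ElasticNet(
            alpha=lam / (2.0 * n),
            l1_ratio=alpha,
            fit_intercept=config.fit_intercept,
            max_iter=200_000,
            tol=1e-10,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def _prepare_fold(
    X: np.ndarray, y: np.ndarray, test_index: int, config: EnetConfig, fold_seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Training data for one LOO fold: holdout removed, then standardized
    on the training rows only, then (optionally) SMOTE-resampled.

    Returns (X_train, y_train, center, scale); the left-out sample never
    contributes to standardization statistics or synthetic points.
    """
    mask = np.ones(len(y), dtype=bool)
    mask[test_index] = False
    X_tr, y_tr = X[mask], y[mask]
    center, scale = _standardizer(X_tr, config)
    X_tr = (X_tr - center) / scale
    if config.imbalance == "smote":
        X_tr, y_tr = smote_oversample(X_tr, y_tr, k=config.smote_k, seed=fold_seed)
    return X_tr, y_tr, center, scale


def _standardizer(X: np.ndarray, config: EnetConfig) -> tuple[np.ndarray, np.ndarray]:
    if not config.standardize_inputs:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return center, scale


def train_enet(
    X: pd.DataFrame,
    y: Sequence,
    config: EnetConfig,
    class_order: Sequence | None = None,
) -> EnetResult:
    """Leave-one-out-tuned elastic-net classifier (or gaussian regression).

    For every left-out sample the model is fit on the remainder — with the
    configured imbalance handling applied to the training fold only —
    across the (alpha, lambda) grid; the pair minimizing the mean LOO
    deviance is selected (ties go to the larger lambda, i.e. the sparser
    model).  Final coefficients come from a fit on all data at the selected
    pair, and the per-fold holdout predictions at that pair provide the
    classification metrics.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    sample_index = (
        list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(y)))
    )
    X_arr = np.asarray(X, dtype=float)
    y_arr = np.asarray(y)
    if not np.isfinite(X_arr).all():
        raise ValueError("feature matrix contains non-finite values")
    n = len(y_arr)

    if config.family == "gaussian":
        return _train_gaussian(X_arr, y_arr, config, feature_names)

    classes, counts = np.unique(y_arr, return_counts=True)
    if class_order is not None:
        if set(class_order) != set(classes):
            raise ValueError("class_order must cover exactly the observed classes")
        classes = np.asarray(list(class_order))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        bad = [c for c, k in zip(np.unique(y_arr), counts) if k < 2]
        raise ValueError(
            f"class(es) {bad} have a single sample; merge or remove them"
        )
    if len(classes) > 2 and config.family == "binomial":
        raise ValueError("binomial family requires exactly 2 classes")

    alphas, lambdas = config.alphas, config.lambdas
    seeds = np.random.SeedSequence(config.seed).generate_state(n) % (2**31)
    # deviance[i_alpha, i_lambda, fold]; probs[...] for metric extraction
    deviance = np.zeros((len(alphas), len(lambdas), n))
    probs = np.zeros((len(alphas), len(lambdas), n, len(classes)))
    for fold in range(n):
        X_tr, y_tr, center, scale = _prepare_fold(
            X_arr, y_arr, fold, config, int(seeds[fold])
        )
        x_test = (X_arr[fold] - center) / scale
        for ia, a in enumerate(alphas):
            for il, lam in enumerate(lambdas):
                model = _fit_classifier(X_tr, y_tr, a, lam, config, classes)
                p = model.predict_proba(x_test[None, :])[0]
                aligned = np.full(len(classes), 1e-12)
                for cls, pk in zip(model.classes_, p):
                    aligned[list(classes).index(cls)] = pk
                probs[ia, il, fold] = aligned
                p_true = aligned[list(classes).index(y_arr[fold])]
                deviance[ia, il, fold] = -2.0 * np.log(max(p_true, 1e-12))

    mean_dev = deviance.mean(axis=2)
    # ties -> larger lambda (sparser), then smaller alpha; scan accordingly
    best = (0, 0)
    best_val = np.inf
    for il in range(len(lambdas) - 1, -1, -1):
        for ia in range(len(alphas)):
            if mean_dev[ia, il] < best_val - 1e-12:
                best_val = mean_dev[ia, il]
                best = (ia, il)
    ia, il = best
    selected_alpha, selected_lambda = float(alphas[ia]), float(lambdas[il])

    # final fit on all data at the selected pair
    center, scale = _standardizer(X_arr, config)
    X_std = (X_arr - center) / scale
    X_fit, y_fit = X_std, y_arr
    if config.imbalance == "smote":
        X_fit, y_fit = smote_oversample(
            X_fit, y_fit, k=config.smote_k, seed=config.seed
        )
    final = _fit_classifier(X_fit, y_fit, selected_alpha, selected_lambda, config, classes)

    coef = np.asarray(final.coef_)
    if coef.shape[0] == 1 and len(classes) == 2:
        # sklearn binary: one row for the second of model.classes_
        row_classes = [final.classes_[1]]
    else:
        row_classes = list(final.classes_)
    coefficients = pd.DataFrame(coef, index=row_classes, columns=feature_names)
    # order rows by the requested class order where applicable
    coefficients = coefficients.loc[[c for c in classes if c in coefficients.index]]

    loo_pred_labels = np.asarray(
        [classes[np.argmax(probs[ia, il, f])] for f in range(n)]
    )
    loo = pd.DataFrame(
        probs[ia, il],
        index=pd.Index(sample_index, name="sample_id"),
        columns=[f"p_{c}" for c in classes],
    )
    loo.insert(0, "predicted", loo_pred_labels)
    loo.insert(0, "true", y_arr)

    metrics = classification_metrics(
        y_arr, loo_pred_labels, classes=list(classes), weights=config.kappa_weights
    )
    path = pd.DataFrame(
        mean_dev,
        index=pd.Index(alphas, name="alpha"),
        columns=pd.Index(lambdas, name="lambda"),
    )
    result = EnetResult(
        coefficients=coefficients,
        intercepts=np.atleast_1d(final.intercept_),
        selected_lambda=selected_lambda,
        selected_alpha=selected_alpha,
        classes=list(classes),
        loo_predictions=loo,
        confusion=metrics["confusion"],
        accuracy=metrics["accuracy"],
        accuracy_ci=metrics["accuracy_ci"],
        kappa_unweighted=metrics["kappa_unweighted"],
        kappa_weighted=metrics["kappa_weighted"],
        deviance_path=path,
    )
    result.importance = importance_scores(result)
    return result


def _train_gaussian(
    X: np.ndarray, y: np.ndarray, config: EnetConfig, feature_names: list[str]
) -> EnetResult:
    """Least-squares family: LOO-MSE lambda selection, then a full-data fit."""
    alphas, lambdas = config.alphas, config.lambdas
    n = len(y)
    if len(lambdas) > 1 or len(alphas) > 1:
        sse = np.zeros((len(alphas), len(lambdas)))
        for fold in range(n):
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            center, scale = _standardizer(X[mask], config)
            X_tr = (X[mask] - center) / scale
            x_te = (X[fold] - center) / scale
            for ia, a in enumerate(alphas):
                for il, lam in enumerate(lambdas):
                    model = _fit_gaussian(X_tr, y[mask], a, lam, config)
                    sse[ia, il] += float(
                        (model.predict(x_te[None, :])[0] - y[fold]) ** 2
                    )
        ia, il = np.unravel_index(np.argmin(sse), sse.shape)
    else:
        ia = il = 0
    center, scale = _standardizer(X, config)
    model = _fit_gaussian((X - center) / scale, y, alphas[ia], lambdas[il], config)
    coefficients = pd.DataFrame(
        np.atleast_2d(model.coef_), index=["response"], columns=feature_names
    )
    result = EnetResult(
        coefficients=coefficients,
        intercepts=np.atleast_1d(getattr(model, "intercept_", 0.0)),
        selected_lambda=float(lambdas[il]),
        selected_alpha=float(alphas[ia]),
        classes=["response"],
    )
    result.importance = importance_scores(result)
    return result


def importance_scores(result: EnetResult) -> pd.DataFrame:
    """Per-class and overall feature importance from |beta|.

    Per-class scores are |beta| rescaled by a single common factor chosen
    so the maximum *overall* score (the per-feature sum over classes)
    equals 100; zero coefficients score 0.  The overall column is therefore
    exactly the row-sum of the per-class columns.
    """
    absbeta = result.coefficients.abs()
    overall = absbeta.sum(axis=0)
    top = overall.max()
    if not top > 0:
        warnings.warn("all coefficients are zero; importance is all-zero", stacklevel=2)
        scale = 0.0
    else:
        scale = 100.0 / top
    table = (absbeta * scale).T
    table.columns = [str(c) for c in result.coefficients.index]
    table["Overall"] = overall * scale
    table.index.name = "feature_id"
    return table.sort_values("Overall", ascending=False)


def classification_metrics(
    y_true: Sequence,
    y_pred: Sequence,
    classes: Sequence | None = None,
    weights: str = "linear",
) -> dict:
    """Accuracy with an exact (Clopper–Pearson) 95% CI, Cohen's kappa
    (unweighted and ordinal-weighted) and the confusion matrix.

    The weighted kappa discounts near-miss errors along the class ordering
    given by ``classes`` — for disease stages, the control < non-lesional <
    established < advanced chain.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("predictions and truth must align")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    n = len(y_true)
    correct = int((y_true == y_pred).sum())
    accuracy = correct / n
    lo, hi = proportion_confint(correct, n, alpha=0.05, method="beta")
    confusion = pd.DataFrame(
        confusion_matrix(y_true, y_pred, labels=classes),
        index=pd.Index(classes, name="true"),
        columns=pd.Index(classes, name="predicted"),
    )
    if len(set(y_true)) < 2:
        warnings.warn("single-class truth: kappa undefined (NaN)", stacklevel=2)
        kappa = kappa_w = float("nan")
    else:
        kappa = cohen_kappa_score(y_true, y_pred, labels=classes)
        kappa_w = cohen_kappa_score(y_true, y_pred, labels=classes, weights=weights)
    return {
        "accuracy": accuracy,
        "accuracy_ci": (float(lo), float(hi)),
        "kappa_unweighted": float(kappa),
        "kappa_weighted": float(kappa_w),
        "confusion": confusion,
    }
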