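"""K-nearest-neighbors classification (from scratch) and SVM comparison.

Evaluation follows a fixed protocol: a stratified 80/20 train/test split,
stratified 5-fold cross-validation inside the 80% (fold accuracies and
their mean), then a final model fitted on the full training portion and
scored once on the untouched 20%.  Feature standardization (z-score) is
refit on the training rows of every fold — the held-out rows never
influence the scaler.

The K-NN distance rule is deterministic: Euclidean metric, distance ties
broken by lower training-row index, vote ties broken by the single nearest
neighbor's label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .errors import InvalidArgumentError
from .stats import ConfusionMatrix, accuracy_from_cm

__all__ = [
    "SplitPlan",
    "KnnConfig",
    "EvalReport",
    "Standardization",
    "standardize_fit_apply",
    "knn_predict",
    "cross_validate",
    "svm_evaluate",
]

POSITIVE_LABEL = "calcified"


@dataclass(frozen=True)
class SplitPlan:
    test_fraction: float = 0.20
    n_folds: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise InvalidArgumentError("test_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise InvalidArgumentError("n_folds must be >= 2")


@dataclass(frozen=True)
class KnnConfig:
    k_neighbors: int = 3
    metric: str = "euclidean"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise InvalidArgumentError("k_neighbors must be >= 1")
        if self.metric != "euclidean":
            raise InvalidArgumentError("only the euclidean metric is supported")


@dataclass
class EvalReport:
    fold_accuracies: list[float]
    cv_mean: float
    test_accuracy: float
    confusion: ConfusionMatrix
    feature_set: list[str]
    classifier: str = "knn"

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "feature_set": list(self.feature_set),
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "cv_mean": float(self.cv_mean),
            "test_accuracy": float(self.test_accuracy),
            "confusion": {
                "tp": self.confusion.tp,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
            },
        }


class Standardization(NamedTuple):
    scaled_train: np.ndarray
    scaled_other: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    kept_columns: np.ndarray  # indices into the original columns


def standardize_fit_apply(
    train_features: np.ndarray, other_features: np.ndarray
) -> Standardization:
    """Z-score columns using training statistics only (no leakage).

    Zero-variance training columns carry no distance information and are
    dropped from both arrays with a warning.
    """
    train = np.atleast_2d(np.asarray(train_features, dtype=float))
    other = np.atleast_2d(np.asarray(other_features, dtype=float))
    if train.shape[0] < 2:
        raise InvalidArgumentError("training matrix needs at least 2 rows")
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=0)
    # variance at rounding-noise level counts as zero
    nonzero = sds > 1e-9 * np.maximum(1.0, np.abs(means))
    keep = np.flatnonzero(nonzero)
    if keep.size < sds.size:
        dropped = np.flatnonzero(~nonzero)
        warnings.warn(
            f"dropping zero-variance feature column(s) {dropped.tolist()}",
            stacklevel=2,
        )
    if keep.size == 0:
        raise InvalidArgumentError("all feature columns have zero variance")
    means, sds = means[keep], sds[keep]
    return Standardization(
        scaled_train=(train[:, keep] - means) / sds,
        scaled_other=(other[:, keep] - means) / sds,
        means=means,
        sds=sds,
        kept_columns=keep,
    )


def knn_predict(
    train_X: np.ndarray,
    train_y: Sequence,
    query_X: np.ndarray,
    cfg: KnnConfig = KnnConfig(),
) -> np.ndarray:
    """Majority-vote K-NN prediction with deterministic tie-breaking."""
    X = np.atleast_2d(np.asarray(train_X, dtype=float))
    Q = np.atleast_2d(np.asarray(query_X, dtype=float))
    y = np.asarray(train_y)
    if cfg.k_neighbors > X.shape[0]:
        raise InvalidArgumentError(
            f"k={cfg.k_neighbors} exceeds {X.shape[0]} training rows"
        )
    d = cdist(Q, X, metric="euclidean")
    # stable sort: equal distances resolve to the lower training-row index
    order = np.argsort(d, axis=1, kind="stable")[:, : cfg.k_neighbors]
    preds = []
    for row in order:
        votes = y[row]
        labels, counts = np.unique(votes, return_counts=True)
        winners = labels[counts == counts.max()]
        preds.append(votes[0] if len(winners) > 1 else winners[0])
    return np.asarray(preds)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    pos = POSITIVE_LABEL if POSITIVE_LABEL in set(np.asarray(y_true)) else sorted(
        set(np.asarray(y_true))
    )[-1]
    t_pos = np.asarray(y_true) == pos
    p_pos = np.asarray(y_pred) == pos
    return ConfusionMatrix(
        tp=int(np.sum(t_pos & p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
    )


def _as_matrix(
    features: pd.DataFrame | np.ndarray, feature_subset: Sequence[str] | None
) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        cols = list(feature_subset) if feature_subset is not None else list(features.columns)
        return features[cols].to_numpy(dtype=float), cols
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if feature_subset is not None:
        idx = [int(i) for i in feature_subset]
        return X[:, idx], [str(i) for i in idx]
    return X, [str(i) for i in range(X.shape[1])]


def _fit_score(
    fit_X: np.ndarray,
    fit_y: np.ndarray,
    eval_X: np.ndarray,
    eval_y: np.ndarray,
    predictor,
    standardize: bool,
) -> tuple[float, ConfusionMatrix]:
    if standardize:
        std = standardize_fit_apply(fit_X, eval_X)
        fit_X, eval_X = std.scaled_train, std.scaled_other
    pred = predictor(fit_X, fit_y, eval_X)
    cm = _confusion(eval_y, pred)
    return accuracy_from_cm(cm), cm


def _evaluate_protocol(
    features,
    labels,
    plan: SplitPlan,
    predictor,
    feature_names: list[str],
    classifier: str,
    standardize: bool,
) -> EvalReport:
    X, names = features, feature_names
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("both classes must be present")
    mask = ~np.isnan(X).any(axis=1)  # listwise per model on the selected columns
    X, y = X[mask], y[mask]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        test_size=plan.test_fraction,
        random_state=plan.seed,
        shuffle=True,
        stratify=y if plan.stratified else None,
    )
    skf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=plan.seed)
    fold_accuracies = []
    for fit_idx, val_idx in skf.split(X_tr, y_tr):
        if len(np.unique(y_tr[fit_idx])) < 2:
            raise InvalidArgumentError("a CV fold lost one of the classes")
        acc, _ = _fit_score(
            X_tr[fit_idx], y_tr[fit_idx], X_tr[val_idx], y_tr[val_idx],
            predictor, standardize,
        )
        fold_accuracies.append(acc)
    test_acc, cm = _fit_score(X_tr, y_tr, X_te, y_te, predictor, standardize)
    return EvalReport(
        fold_accuracies=fold_accuracies,
        cv_mean=float(np.mean(fold_accuracies)),
        test_accuracy=test_acc,
        confusion=cm,
        feature_set=names,
        classifier=classifier,
    )


def cross_validate(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence,
    plan: SplitPlan = SplitPlan(),
    cfg: KnnConfig = KnnConfig(),
    feature_subset: Sequence[str] | None = None,
) -> EvalReport:
    """Full split/CV/test protocol for the from-scratch K-NN classifier."""
    X, names = _as_matrix(features, feature_subset)

    def predictor(fit_X, fit_y, eval_X):
        return knn_predict(fit_X, fit_y, eval_X, cfg)

    return _evaluate_protocol(
        X, labels, plan, predictor, names, f"knn_k{cfg.k_neighbors}", cfg.standardize
    )


def svm_evaluate(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence,
    plan: SplitPlan = SplitPlan(),
    kernel: str = "polynomial",
    degree: int = 3,
    feature_subset: Sequence[str] | None = None,
    standardize: bool = True,
) -> EvalReport:
    """Same protocol with a polynomial-kernel SVM as comparison baseline."""
    if kernel not in ("polynomial", "poly"):
        raise InvalidArgumentError("kernel must be 'polynomial'")
    X, names = _as_matrix(features, feature_subset)

    def predictor(fit_X, fit_y, eval_X):
        model = SVC(kernel="poly", degree=degree, coef0=1.0)
        model.fit(fit_X, fit_y)
        return model.predict(eval_X)

    return _evaluate_protocol(
        X, labels, plan, predictor, names, f"svm_poly{degree}", standardize
    )
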