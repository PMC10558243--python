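"""Bladder-state classification: model zoo, nested CV, BA, Gini importance.

Four classifier families are compared — random forest (RF), support vector
machine (SVM), k-nearest neighbours (KNN) and a multilayer perceptron (MLP) —
each with a fixed hyperparameter grid. Generalisation is estimated by nested
cross-validation with temporally contiguous, class-stratified folds: the outer
loop holds out one contiguous block per class; the inner loop slides a
contiguous validation block along the time dimension of the outer-training
data to pick the grid point with the best mean inner balanced accuracy, which
is then refit on the whole outer-training set and scored once on the held-out
block. Standardisation and row shuffling happen inside each fold, fitted on
that fold's training rows only, so no information flows from evaluation data
into the model.

Balanced accuracy (BA) is the unweighted mean of the three per-class recalls,
robust to residual class imbalance. For random forests, per-column Gini
importance (mean decrease in impurity) is aggregated into channel-averaged
per-feature scores and per-active-site weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ParameterGrid
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, FeatureTable
from .synth import STATES

MODEL_KINDS = ("RF", "SVM", "KNN", "MLP")

__all__ = [
    "MODEL_KINDS",
    "ModelGrid",
    "BladderStateDecoder",
    "CVReport",
    "ImportanceReport",
    "confusion_matrix_3",
    "balanced_accuracy",
    "nested_cv",
    "compare_models",
    "gini_importance",
]

_DEFAULT_GRIDS = {
    "RF": {"n_estimators": [50, 100, 200, 300], "max_depth": [5, 10, 20, 30]},
    "SVM": {"kernel": ["sigmoid", "rbf"], "C": [1e-3, 1e-2, 1e-1, 1.0]},
    "KNN": {"n_neighbors": [3, 5, 7, 9, 11]},
    "MLP": {
        "hidden_layer_sizes": [
            (128, 128, 128, 128),
            (128, 256, 256, 128),
            (128, 256, 512, 128),
            (128, 512, 512, 128),
            (128, 256, 512, 512),
        ]
    },
}

_ALLOWED_KEYS = {kind: set(grid) for kind, grid in _DEFAULT_GRIDS.items()}


@dataclass(frozen=True)
class ModelGrid:
    """A classifier family plus its hyperparameter search space.

    ``metadata`` records interpretation choices (e.g. that the SVM
    regularisation candidates are used directly as the C strength, which in
    sklearn's convention is the inverse of the penalty weight).
    """

    model_kind: str
    grid: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        unknown = set(self.grid) - _ALLOWED_KEYS[self.model_kind]
        if unknown:
            raise ValueError(
                f"unknown hyperparameters for {self.model_kind}: {sorted(unknown)}"
            )
        if not self.grid:
            object.__setattr__(self, "grid", dict(_DEFAULT_GRIDS[self.model_kind]))
        if self.model_kind == "SVM":
            meta = dict(self.metadata)
            meta.setdefault("C_convention", "regularization candidates used as sklearn C (inverse penalty strength)")
            object.__setattr__(self, "metadata", meta)

    @classmethod
    def default(cls, model_kind: str) -> "ModelGrid":
        return cls(model_kind=model_kind)

    def combinations(self) -> list:
        """Deterministically ordered list of hyperparameter dicts."""
        return list(ParameterGrid(self.grid))


class BladderStateDecoder(ClassifierMixin, BaseEstimator):
    """Sklearn-style front end over the four classifier families.

    The flat parameter namespace covers all four families (each family only
    reads its own parameters), so nested CV can drive the whole zoo through
    ``set_params``. MLP training is adam with learning rate 1e-3, at most 200
    epochs and early stopping (patience 20) on an internal validation split.
    """

    def __init__(
        self,
        model_kind: str = "RF",
        n_estimators: int = 100,
        max_depth: int | None = 20,
        kernel: str = "rbf",
        C: float = 1.0,
        n_neighbors: int = 5,
        hidden_layer_sizes: tuple = (128, 128, 128, 128),
        learning_rate_init: float = 1e-3,
        max_iter: int = 200,
        random_state: int | None = None,
    ):
        self.model_kind = model_kind
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.kernel = kernel
        self.C = C
        self.n_neighbors = n_neighbors
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate_init = learning_rate_init
        self.max_iter = max_iter
        self.random_state = random_state

    def _build(self):
        if self.model_kind == "RF":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                max_features="sqrt",
                random_state=self.random_state,
            )
        if self.model_kind == "SVM":
            return SVC(kernel=self.kernel, C=self.C, random_state=self.random_state)
        if self.model_kind == "KNN":
            return KNeighborsClassifier(n_neighbors=self.n_neighbors)
        if self.model_kind == "MLP":
            return MLPClassifier(
                hidden_layer_sizes=tuple(self.hidden_layer_sizes),
                solver="adam",
                learning_rate_init=self.learning_rate_init,
                max_iter=self.max_iter,
                early_stopping=True,
                n_iter_no_change=20,
                validation_fraction=0.1,
                random_state=self.random_state,
            )
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.model_ = self._build()
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    @property
    def feature_importances_(self):
        check_is_fitted(self, "model_")
        if self.model_kind != "RF":
            raise AttributeError("feature importances are defined for RF only")
        return self.model_.feature_importances_


def confusion_matrix_3(y_true, y_pred, classes=STATES) -> np.ndarray:
    """3×3 confusion matrix, rows = true class, columns = predicted class."""
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        cm[index[t], index[p]] += 1
    return cm


def balanced_accuracy(cm: np.ndarray, classes=STATES) -> float:
    """Unweighted mean of per-class recalls from a confusion matrix.

    Recall of class n is TP / (TP + FN), i.e. the diagonal entry divided by
    its row sum; BA averages the recalls over the classes so every class
    counts equally regardless of its prevalence.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    row_sums = cm.sum(axis=1)
    empty = np.flatnonzero(row_sums == 0)
    if empty.size:
        names = [classes[i] if i < len(classes) else str(i) for i in empty]
        raise ValueError(f"no true instances of class(es): {names}")
    recalls = np.diag(cm) / row_sums
    return float(recalls.mean())


@dataclass
class ImportanceReport:
    """Gini importances: per column, channel-averaged per feature, per AS."""

    per_column: dict
    per_feature: dict
    per_channel: dict

    @classmethod
    def from_columns(cls, values, column_names) -> "ImportanceReport":
        values = np.asarray(values, dtype=float)
        if values.shape[0] != len(column_names):
            raise ValueError("one importance per column required")
        if np.any(values < 0):
            raise ValueError("importances must be non-negative")
        total = values.sum()
        if total <= 0:
            raise ValueError("importances sum to zero")
        values = values / total
        per_column = dict(zip(column_names, values.tolist()))
        per_feature: dict = {f: [] for f in FEATURE_NAMES}
        per_channel: dict = {}
        for name, v in per_column.items():
            ch, feat = name.split("_", 1)
            per_feature[feat].append(v)
            per_channel[ch] = per_channel.get(ch, 0.0) + v
        per_feature = {f: float(np.mean(v)) for f, v in per_feature.items() if v}
        return cls(per_column=per_column, per_feature=per_feature, per_channel=per_channel)

    def top_features(self, k: int = 9) -> list:
        return sorted(self.per_feature, key=self.per_feature.get, reverse=True)[:k]

    def to_dict(self) -> dict:
        return {
            "per_column": self.per_column,
            "per_feature": self.per_feature,
            "per_channel": self.per_channel,
        }


def gini_importance(model, column_names) -> ImportanceReport:
    """Importance report from a fitted random forest.

    Accepts a fitted :class:`BladderStateDecoder` (RF kind) or a fitted
    ``RandomForestClassifier``; any other model is rejected.
    """
    if isinstance(model, BladderStateDecoder):
        if model.model_kind != "RF":
            raise TypeError("Gini importance requires a random forest model")
        forest = model.model_
    elif isinstance(model, RandomForestClassifier):
        forest = model
    else:
        raise TypeError("Gini importance requires a random forest model")
    check_is_fitted(forest)
    return ImportanceReport.from_columns(forest.feature_importances_, column_names)


@dataclass
class CVReport:
    """Outcome of one nested cross-validation run."""

    model_kind: str
    fold_ba: list
    confusions: list
    selected_params: list
    fold_test_sizes: list
    n_outer: int
    n_inner: int
    seed: int
    importance: ImportanceReport | None = None

    @property
    def mean_ba(self) -> float:
        return float(np.mean(self.fold_ba))

    @property
    def median_ba(self) -> float:
        return float(np.median(self.fold_ba))

    @property
    def iqr_ba(self) -> float:
        q1, q3 = np.percentile(self.fold_ba, [25, 75])
        return float(q3 - q1)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "fold_ba": [float(b) for b in self.fold_ba],
            "mean_ba": self.mean_ba,
            "median_ba": self.median_ba,
            "iqr_ba": self.iqr_ba,
            "confusions": [np.asarray(c).tolist() for c in self.confusions],
            "selected_params": [_jsonable(p) for p in self.selected_params],
            "fold_test_sizes": [int(s) for s in self.fold_test_sizes],
            "n_outer": self.n_outer,
            "n_inner": self.n_inner,
            "seed": self.seed,
            "class_order": list(STATES),
            "importance": None if self.importance is None else self.importance.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, sort_keys=True)


def _jsonable(params: dict) -> dict:
    return {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in sorted(params.items())
    }


def temporal_folds(labels, n_folds: int) -> list:
    """Contiguous-in-time, class-stratified fold index sets.

    Rows are assumed time-ordered within each class; each class's row indices
    are cut into ``n_folds`` contiguous blocks and fold k takes block k of
    every class. Deterministic given the labels alone, so every model
    evaluated on the same table shares identical folds.
    """
    labels = np.asarray(labels)
    present = [s for s in STATES if np.any(labels == s)]
    if set(present) != set(STATES):
        missing = sorted(set(STATES) - set(present))
        raise ValueError(f"classes missing from table: {missing}")
    folds = [[] for _ in range(n_folds)]
    for state in STATES:
        idx = np.flatnonzero(labels == state)
        if idx.size < n_folds:
            raise ValueError(
                f"class {state!r} has {idx.size} windows, fewer than {n_folds} folds"
            )
        for k, block in enumerate(np.array_split(idx, n_folds)):
            folds[k].append(block)
    return [np.concatenate(blocks) for blocks in folds]


def _standardize_arrays(X_train, X_eval):
    mean = X_train.mean(axis=0)
    sd = np.maximum(X_train.std(axis=0), 1e-12)
    return (X_train - mean) / sd, (X_eval - mean) / sd, (mean, sd)


def nested_cv(
    table: FeatureTable,
    grid: ModelGrid,
    n_outer: int = 10,
    n_inner: int = 3,
    seed: int = 0,
    audit: Callable | None = None,
) -> CVReport:
    """Nested cross-validation with temporal folds and in-fold standardisation.

    ``audit``, if given, is called with instrumentation events (fold indices,
    fitted scaler parameters) so leakage tests can verify that scalers are fit
    on training rows only. The table must be unstandardised and unshuffled,
    rows in time order within each class.
    """
    if table.scaler is not None:
        raise ValueError("nested_cv requires an unstandardised table")
    if n_outer < 2 or n_inner < 2:
        raise ValueError("n_outer and n_inner must be >= 2")
    X, y = table.X, table.labels
    outer = temporal_folds(y, n_outer)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_outer)]
    combos = grid.combinations()

    fold_ba, confusions, selected, sizes = [], [], [], []
    importances = []
    for k, test_idx in enumerate(outer):
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        train_idx = np.flatnonzero(mask)
        rng = np.random.default_rng(fold_seeds[k])

        best_combo = combos[0]
        if len(combos) > 1:
            inner = temporal_folds(y[train_idx], n_inner)
            prepared = []
            for j, val_rel in enumerate(inner):
                m = np.ones(train_idx.size, dtype=bool)
                m[val_rel] = False
                itr = train_idx[m]
                val = train_idx[val_rel]
                Xtr, Xval, _ = _standardize_arrays(X[itr], X[val])
                perm = rng.permutation(itr.size)
                prepared.append((Xtr[perm], y[itr][perm], Xval, y[val]))
            mean_inner = []
            for combo in combos:
                bas = []
                for Xtr, ytr, Xval, yval in prepared:
                    est = BladderStateDecoder(
                        model_kind=grid.model_kind,
                        random_state=fold_seeds[k],
                        **combo,
                    ).fit(Xtr, ytr)
                    cm = confusion_matrix_3(yval, est.predict(Xval))
                    bas.append(balanced_accuracy(cm))
                mean_inner.append(float(np.mean(bas)))
            best_combo = combos[int(np.argmax(mean_inner))]

        Xtr, Xte, scaler = _standardize_arrays(X[train_idx], X[test_idx])
        perm = rng.permutation(train_idx.size)
        est = BladderStateDecoder(
            model_kind=grid.model_kind, random_state=fold_seeds[k], **best_combo
        ).fit(Xtr[perm], y[train_idx][perm])
        cm = confusion_matrix_3(y[test_idx], est.predict(Xte))
        if audit is not None:
            audit(
                {
                    "event": "outer_fold",
                    "fold": k,
                    "train_idx": train_idx,
                    "test_idx": test_idx,
                    "scaler_mean": scaler[0],
                    "scaler_sd": scaler[1],
                    "selected": best_combo,
                }
            )
        fold_ba.append(balanced_accuracy(cm))
        confusions.append(cm)
        selected.append(best_combo)
        sizes.append(test_idx.size)
        if grid.model_kind == "RF":
            importances.append(est.feature_importances_)

    importance = None
    if importances:
        importance = ImportanceReport.from_columns(
            np.mean(importances, axis=0), table.column_names
        )
    return CVReport(
        model_kind=grid.model_kind,
        fold_ba=fold_ba,
        confusions=confusions,
        selected_params=selected,
        fold_test_sizes=sizes,
        n_outer=n_outer,
        n_inner=n_inner,
        seed=seed,
        importance=importance,
    )


def compare_models(
    table: FeatureTable,
    grids: list | None = None,
    n_outer: int = 10,
    n_inner: int = 3,
    seed: int = 0,
) -> tuple:
    """Run nested CV for several model families on identical folds.

    Returns ``(reports, ranking)`` where ``reports`` maps model kind to its
    :class:`CVReport` and ``ranking`` lists kinds by decreasing mean BA, ties
    broken by smaller interquartile range.
    """
    if grids is None:
        grids = [ModelGrid.default(kind) for kind in MODEL_KINDS]
    reports = {
        g.model_kind: nested_cv(table, g, n_outer=n_outer, n_inner=n_inner, seed=seed)
        for g in grids
    }
    ranking = sorted(
        reports, key=lambda k: (-reports[k].mean_ba, reports[k].iqr_ba, k)
    )
    return reports, ranking
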