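"""Multiclass training and evaluation: 10-fold CV, per-sign splits, metrics.

Algorithms are registered by name (``knn``, ``random_forest``, ``mlp``,
``naive_bayes``, ``svm``) and always run behind a z-score standardizer fitted
on training data only (feature scales span orders of magnitude).  Metrics
follow the Weka conventions: accuracy in percent, Cohen's kappa from the
pooled confusion matrix, and RMSE over per-instance class-probability rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "EvalResult",
    "SplitProtocol",
    "Model",
    "fit",
    "predict",
    "predict_proba",
    "kappa",
    "rmse_probability",
    "confusion_matrix",
    "cross_validate",
    "split_evaluate",
    "parse_classifier_line",
    "ALGORITHM_DEFAULTS",
]

ALGORITHM_DEFAULTS: dict[str, dict] = {
    "knn": {"k": 3},
    "random_forest": {"n_trees": 100},
    "mlp": {"hidden": 50, "max_iter": 300},
    "naive_bayes": {},
    "svm": {"C": 1.0, "kernel": "rbf"},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm name plus parameter overrides (defaults documented above)."""

    algorithm: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHM_DEFAULTS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; known: {sorted(ALGORITHM_DEFAULTS)}"
            )
        unknown = set(self.params) - set(ALGORITHM_DEFAULTS[self.algorithm])
        if unknown:
            raise ValueError(f"unknown parameters for {self.algorithm}: {sorted(unknown)}")

    def resolved_params(self) -> dict:
        out = dict(ALGORITHM_DEFAULTS[self.algorithm])
        out.update(self.params)
        return out


def parse_classifier_line(line: str) -> ClassifierSpec:
    """Parse one ``algorithms.txt``-style line, e.g. ``knn k=3``."""
    parts = line.split()
    if not parts:
        raise ValueError("empty classifier spec line")
    name = parts[0]
    params: dict = {}
    for tok in parts[1:]:
        if "=" not in tok:
            raise ValueError(f"malformed parameter {tok!r} (expected key=value)")
        key, value = tok.split("=", 1)
        try:
            parsed: object = int(value)
        except ValueError:
            try:
                parsed = float(value)
            except ValueError:
                parsed = value
        params[key] = parsed
    return ClassifierSpec(name, params)


def _build_estimator(spec: ClassifierSpec, seed: int):
    p = spec.resolved_params()
    if spec.algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=int(p["k"]))
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=int(p["n_trees"]), random_state=seed)
    if spec.algorithm == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(int(p["hidden"]),),
            max_iter=int(p["max_iter"]),
            random_state=seed,
        )
    if spec.algorithm == "naive_bayes":
        return GaussianNB()
    if spec.algorithm == "svm":
        return SVC(C=float(p["C"]), kernel=str(p["kernel"]), probability=True, random_state=seed)
    raise AssertionError("unreachable")


@dataclass
class Model:
    """A fitted classifier with its standardization and provenance metadata."""

    spec: ClassifierSpec
    seed: int
    scaler: StandardScaler
    estimator: object
    classes: np.ndarray
    feature_names_hash: str

    @property
    def n_features(self) -> int:
        return self.scaler.mean_.shape[0]


def _hash_names(names: Optional[Sequence[str]]) -> str:
    import hashlib

    if names is None:
        return "unversioned"
    joined = "\x1f".join(names)
    return hashlib.sha256(joined.encode("utf-8")).hexdigest()


def fit(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: Sequence[str],
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> Model:
    """Standardize on the training set, then fit the requested classifier."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 1 or np.any(counts < 1):
        raise ValueError("every class needs at least one training example")
    scaler = StandardScaler().fit(X)
    est = _build_estimator(spec, seed)
    est.fit(scaler.transform(X), y)
    return Model(
        spec=spec,
        seed=seed,
        scaler=scaler,
        estimator=est,
        classes=np.asarray(est.classes_),
        feature_names_hash=_hash_names(feature_names),
    )


def predict_proba(model: Model, X: np.ndarray) -> np.ndarray:
    """Per-class probability rows (nonnegative, each summing to 1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: got {X.shape[1] if X.ndim == 2 else '?'}, "
            f"model expects {model.n_features}"
        )
    proba = model.estimator.predict_proba(model.scaler.transform(X))
    return np.asarray(proba, dtype=float)


def predict(model: Model, X: np.ndarray) -> np.ndarray:
    """Labels as argmax of :func:`predict_proba` (guaranteed consistent)."""
    proba = predict_proba(model, X)
    return model.classes[np.argmax(proba, axis=1)]


def confusion_matrix(y_true: Sequence, y_pred: Sequence, classes: Sequence) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    return mat


def kappa(confusion: np.ndarray) -> float:
    """Cohen's kappa (p_o - p_e) / (1 - p_e) from a confusion matrix."""
    c = np.asarray(confusion, dtype=float)
    if c.size == 0 or c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square and nonempty")
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix must contain at least one count")
    p_o = np.trace(c) / total
    p_e = float(np.sum(c.sum(axis=1) * c.sum(axis=0)) / total**2)
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def rmse_probability(proba: np.ndarray, y_true: Sequence, classes: Sequence) -> float:
    """Root mean squared error over all instance-class probability cells."""
    proba = np.asarray(proba, dtype=float)
    target = np.zeros_like(proba)
    index = {c: i for i, c in enumerate(classes)}
    for i, t in enumerate(y_true):
        target[i, index[t]] = 1.0
    return float(np.sqrt(np.mean((proba - target) ** 2)))


@dataclass
class EvalResult:
    """Accuracy (%), kappa, probability RMSE and the pooled confusion matrix."""

    accuracy: float
    kappa: float
    rmse: float
    confusion: np.ndarray
    classes: list

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "rmse": self.rmse,
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
        }

    def summary(self) -> str:
        return (
            f"accuracy {self.accuracy:.4f}%  kappa {self.kappa:.4f}  "
            f"rmse {self.rmse:.4f}  ({len(self.classes)} classes, "
            f"{int(self.confusion.sum())} instances)"
        )


def _evaluate_pooled(y_true, y_pred, proba, classes) -> EvalResult:
    conf = confusion_matrix(y_true, y_pred, classes)
    accuracy = 100.0 * np.trace(conf) / conf.sum()
    return EvalResult(
        accuracy=float(accuracy),
        kappa=kappa(conf),
        rmse=rmse_probability(proba, y_true, classes),
        confusion=conf,
        classes=list(classes),
    )


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded stratified fold assignment; plain shuffled folds as fallback."""
    classes, counts = np.unique(y, return_counts=True)
    fold_of = np.empty(len(y), dtype=int)
    if counts.min() >= k:
        for c in classes:
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            fold_of[idx] = np.arange(len(idx)) % k
    else:
        idx = rng.permutation(len(y))
        fold_of[idx] = np.arange(len(y)) % k
    return [np.flatnonzero(fold_of == f) for f in range(k)]


def cross_validate(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: Sequence[str],
    k: int = 10,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> EvalResult:
    """Stratified k-fold CV; per-fold test predictions pooled into one matrix.

    Standardization is refit on each training fold.  Classes with fewer than
    ``k`` examples trigger a fallback to plain shuffled folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    n = len(y)
    pooled_pred = np.empty(n, dtype=y.dtype)
    pooled_proba = np.zeros((n, len(classes)))
    class_index = {c: i for i, c in enumerate(classes)}
    for f, test_idx in enumerate(folds):
        if len(test_idx) == 0:
            continue
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        model = fit(spec, X[train_mask], y[train_mask], seed=seed + f, feature_names=feature_names)
        proba = predict_proba(model, X[test_idx])
        for j, c in enumerate(model.classes):
            pooled_proba[test_idx, class_index[c]] = proba[:, j]
        pooled_pred[test_idx] = model.classes[np.argmax(proba, axis=1)]
    return _evaluate_pooled(y, pooled_pred, pooled_proba, classes)


@dataclass(frozen=True)
class SplitProtocol:
    """Per-sign train/test record counts with a sampling seed."""

    n_train: int
    n_test: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")


def split_evaluate(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: Sequence[str],
    protocol: SplitProtocol,
    feature_names: Optional[Sequence[str]] = None,
) -> EvalResult:
    """Per-sign random split: n_train records to train, n_test of the rest to test."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    rng = np.random.default_rng(protocol.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) < protocol.n_train + protocol.n_test:
            raise ValueError(
                f"class {c!r} has {len(idx)} records; protocol needs "
                f"{protocol.n_train}+{protocol.n_test}"
            )
        perm = rng.permutation(idx)
        train_idx.extend(perm[: protocol.n_train])
        test_idx.extend(perm[protocol.n_train : protocol.n_train + protocol.n_test])
    model = fit(spec, X[train_idx], y[train_idx], seed=protocol.seed, feature_names=feature_names)
    proba_part = predict_proba(model, X[test_idx])
    proba = np.zeros((len(test_idx), len(classes)))
    class_index = {c: i for i, c in enumerate(classes)}
    for j, c in enumerate(model.classes):
        proba[:, class_index[c]] = proba_part[:, j]
    y_pred = model.classes[np.argmax(proba_part, axis=1)]
    return _evaluate_pooled(y[test_idx], y_pred, proba, classes)
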