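"""Stratified cross-validated grid search and metrics.

Every configuration (descriptor parameters x classifier parameters) is
scored by stratified 10-fold cross-validation; the report keeps per-fold
metrics and summarises each configuration as mean +/- std. In ``reduced``
mode the standardiser and PCA are fitted inside each training fold and
applied to the held-out fold, so no test information leaks into the
transform. AUC is the Mann-Whitney probability of correct ranking with ties
counted one half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from octatex.dimreduce import fit_reducer, transform
from octatex.features import FeatureMatrix

KNN_K_GRID = (1, 3, 5, 7, 9)
KNN_METRICS = ("euclidean", "manhattan", "chebyshev")
SVM_C_GRID = (0.1, 1, 5, 10, 50, 100)
SVM_KERNELS = ("linear", "rbf", "poly")
SVM_GAMMA_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 0.1, 1)
SVM_DEGREE_GRID = (2, 3, 4, 5, 6, 7, 8, 9)


@dataclass(frozen=True)
class ClassifierSpec:
    """One grid point: classifier family plus hyper-parameters."""

    family: str  # "knn" | "svm"
    params: tuple[tuple[str, object], ...]

    @property
    def key(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in self.params)
        return f"{self.family}({inner})"

    def build(self):
        p = dict(self.params)
        if self.family == "knn":
            return KNeighborsClassifier(n_neighbors=p["k"], metric=p["metric"], algorithm="brute")
        if self.family == "svm":
            kwargs = {"C": p["C"], "kernel": p["kernel"]}
            if p["kernel"] in ("rbf", "poly"):
                kwargs["gamma"] = p["gamma"]
            if p["kernel"] == "poly":
                kwargs["degree"] = p["degree"]
            return SVC(**kwargs)
        raise ValueError(f"unknown classifier family {self.family!r}")


def knn_grid() -> list[ClassifierSpec]:
    """5 neighbour counts x 3 distance metrics = 15 grid points."""
    return [
        ClassifierSpec("knn", (("k", k), ("metric", m)))
        for k in KNN_K_GRID
        for m in KNN_METRICS
    ]


def svm_grid() -> list[ClassifierSpec]:
    """linear: C; rbf: C x gamma; poly: C x gamma x degree."""
    out = []
    for C in SVM_C_GRID:
        out.append(ClassifierSpec("svm", (("C", C), ("kernel", "linear"))))
    for C in SVM_C_GRID:
        for g in SVM_GAMMA_GRID:
            out.append(ClassifierSpec("svm", (("C", C), ("kernel", "rbf"), ("gamma", g))))
    for C in SVM_C_GRID:
        for g in SVM_GAMMA_GRID:
            for d in SVM_DEGREE_GRID:
                out.append(ClassifierSpec("svm", (("C", C), ("kernel", "poly"), ("gamma", g), ("degree", d))))
    return out


def full_classifier_grid() -> list[ClassifierSpec]:
    return knn_grid() + svm_grid()


@dataclass(frozen=True)
class EvaluationConfig:
    folds: int = 10
    seed: int = 42
    mode: str = "whole"  # "whole" | "reduced"
    retention_threshold: float = 95.0
    classifiers: tuple[ClassifierSpec, ...] = ()
    fit_reduction_per_fold: bool = True

    def __post_init__(self):
        if self.mode not in ("whole", "reduced"):
            raise ValueError(f"mode must be 'whole' or 'reduced', got {self.mode!r}")
        if not self.classifiers:
            object.__setattr__(self, "classifiers", tuple(full_classifier_grid()))


def stratified_kfold(labels: np.ndarray, K: int = 10, seed: int = 42) -> list[np.ndarray]:
    """Disjoint stratified test-index sets covering all samples.

    Within each class, indices are shuffled with ``seed`` and dealt across
    folds so per-fold class counts differ from the ideal by at most one.
    """
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        n_cls = int(np.sum(labels == cls))
        if n_cls < K:
            raise ValueError(f"class {cls} has {n_cls} members, fewer than K={K}")
    splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    return [np.sort(test_idx) for _, test_idx in splitter.split(np.zeros(len(labels)), labels)]


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: probability a positive outscores a negative, ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks -> ties counted 1/2
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def metric_panel(predictions: np.ndarray, scores: np.ndarray, labels: np.ndarray) -> dict:
    """Accuracy, sensitivity, specificity, precision and AUC for one fold.

    Ratios with a zero denominator are reported as 0 with ``degenerate`` set.
    """
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions/labels shape mismatch")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    panel = {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "precision": ratio(tp, tp + fp, "precision"),
        "auc": auc(scores, labels),
    }
    panel["degenerate"] = tuple(degenerate)
    return panel


def _scores_of(clf, X: np.ndarray) -> np.ndarray:
    """Continuous ranking scores: SVM decision value, KNN positive-vote fraction."""
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X), dtype=float)
    proba = clf.predict_proba(X)
    pos_col = list(clf.classes_).index(1)
    return np.asarray(proba[:, pos_col], dtype=float)


METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity", "precision")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    folds: list[np.ndarray],
    mode: str = "whole",
    retention_threshold: float = 95.0,
    fit_reduction_per_fold: bool = True,
) -> list[dict]:
    """Per-fold metric panels for one classifier configuration.

    With ``fit_reduction_per_fold`` (the default) the standardiser and PCA
    are refitted on each training fold; disabling it reproduces the
    whole-dataset fit, which leaks test statistics into the transform.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    all_idx = np.arange(len(y))
    global_model = None
    if mode == "reduced" and not fit_reduction_per_fold:
        global_model = fit_reducer(X, threshold=retention_threshold)
    out = []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        X_tr, X_te = X[train_idx], X[test_idx]
        if mode == "reduced":
            model = global_model or fit_reducer(X_tr, threshold=retention_threshold)
            X_tr = transform(X[train_idx], model)
            X_te = transform(X[test_idx], model)
        clf = spec.build()
        clf.fit(X_tr, y[train_idx])
        preds = np.asarray(clf.predict(X_te), dtype=int)
        scores = _scores_of(clf, X_te)
        out.append(metric_panel(preds, scores, y[test_idx]))
    return out


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    specs: list[ClassifierSpec],
    K: int = 10,
    seed: int = 42,
    mode: str = "whole",
    retention_threshold: float = 95.0,
) -> list[dict]:
    """Selection-free generalisation estimate of the grid-search pipeline.

    For each outer fold the best classifier is chosen by inner stratified CV
    on the training portion only, then scored once on the held-out fold.
    Unlike taking the maximum mean AUC over the grid, the returned per-fold
    panels carry no selection optimism.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    outer = stratified_kfold(y, K=K, seed=seed)
    all_idx = np.arange(len(y))
    panels = []
    for test_idx in outer:
        train_idx = np.setdiff1d(all_idx, test_idx)
        inner_k = min(K, int(np.bincount(y[train_idx]).min()))
        inner = stratified_kfold(y[train_idx], K=inner_k, seed=seed)
        best_spec, best_key = None, None
        for i, spec in enumerate(specs):
            inner_panels = cross_validate(
                X[train_idx], y[train_idx], spec, inner,
                mode=mode, retention_threshold=retention_threshold,
            )
            aucs = np.array([p["auc"] for p in inner_panels])
            key = (-aucs.mean(), aucs.std(), i)
            if best_key is None or key < best_key:
                best_key, best_spec = key, spec
        panel = cross_validate(
            X, y, best_spec, [test_idx], mode=mode, retention_threshold=retention_threshold
        )[0]
        panel["selected"] = best_spec.key
        panels.append(panel)
    return panels


@dataclass
class EvaluationReport:
    """Per-configuration fold metrics, ranked by mean AUC."""

    entries: list[dict] = field(default_factory=list)

    def add(self, descriptor: str, classifier: ClassifierSpec, fold_panels: list[dict]) -> dict:
        summary = {
            "descriptor": descriptor,
            "classifier": classifier.key,
            "folds": fold_panels,
        }
        for m in METRIC_NAMES:
            vals = np.array([p[m] for p in fold_panels], dtype=float)
            summary[f"mean_{m}"] = float(vals.mean())
            summary[f"std_{m}"] = float(vals.std())
        self.entries.append(summary)
        return summary

    @property
    def best(self) -> dict:
        """Max mean AUC; ties broken by smaller std, then entry order."""
        if not self.entries:
            raise ValueError("empty report")
        return min(
            enumerate(self.entries),
            key=lambda t: (-t[1]["mean_auc"], t[1]["std_auc"], t[0]),
        )[1]

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {"best": _strip_folds(self.best), "entries": self.entries}
        payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _strip_folds(entry: dict) -> dict:
    return {k: v for k, v in entry.items() if k != "folds"}


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def run_grid(config: EvaluationConfig, data: FeatureMatrix | dict) -> EvaluationReport:
    """Evaluate every (feature set, classifier) grid point by stratified CV.

    ``data`` is one :class:`FeatureMatrix` or a mapping of descriptor tag to
    matrices (one per descriptor parameter setting); all matrices must share
    labels. Folds are drawn once per feature matrix from its labels with the
    config seed, so results are deterministic.
    """
    if isinstance(data, FeatureMatrix):
        data = {data.fingerprint or "features": data}
    report = EvaluationReport()
    for tag, fm in data.items():
        folds = stratified_kfold(fm.labels, K=config.folds, seed=config.seed)
        for spec in config.classifiers:
            panels = cross_validate(
                fm.D, fm.labels, spec, folds,
                mode=config.mode, retention_threshold=config.retention_threshold,
                fit_reduction_per_fold=config.fit_reduction_per_fold,
            )
            report.add(tag, spec, panels)
    return report
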