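"""Classifier training, repeated cross-validation and evaluation metrics.

The classifier of record is a 100-tree random forest; KNN, Gaussian naive
Bayes and an RBF SVM are available for algorithm comparison, each with the
fixed hyperparameters used throughout this package:

    RF   n_estimators=100
    KNN  n_neighbors=7, weights='uniform', p=2
    GNB  defaults
    SVM  C=10, gamma=0.001, kernel='rbf'

Evaluation follows the repeated stratified ten-fold protocol: per-fold
confusion counts are turned into Recall, Precision, Accuracy, F1 and MCC,

    Recall    = TP / (TP + FN)
    Precision = TP / (TP + FP)
    Accuracy  = (TP + TN) / (TP + FP + TN + FN)
    F1        = 2 * Precision * Recall / (Precision + Recall)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

averaged within each repeat and then across repeats.  MCC with a zero
denominator factor is defined as 0.  The positive class is "circRNA".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve, precision_recall_curve
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import block_columns

__all__ = [
    "ALGORITHMS",
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "ConfusionCounts",
    "MetricsReport",
    "TrainedModelBundle",
    "compute_metrics",
    "confusion_from_labels",
    "make_classifier",
    "train_classifier",
    "predict",
    "repeated_kfold_cv",
    "feature_combination_grid",
    "roc_points",
    "pr_points",
    "save_bundle",
    "load_bundle",
]

POSITIVE_LABEL = "circRNA"
NEGATIVE_LABEL = "non-circRNA"
_BUNDLE_FORMAT = "pcirc-bundle-1"

ALGORITHMS: Dict[str, dict] = {
    "RF": {"n_estimators": 100},
    "KNN": {"n_neighbors": 7, "weights": "uniform", "p": 2},
    "GNB": {},
    "SVM": {"C": 10, "gamma": 0.001, "kernel": "rbf"},
}


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion table; positives are circRNAs."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    recall: float
    precision: float
    accuracy: float
    f1: float
    mcc: float
    auc: Optional[float] = None
    roc_points: Optional[List[Tuple[float, float]]] = None
    pr_points: Optional[List[Tuple[float, float]]] = None

    def to_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def compute_metrics(cc: ConfusionCounts) -> MetricsReport:
    """Scalar metrics from a confusion table.

    Ratios with an empty denominator (e.g. precision with no predicted
    positives) are 0; MCC with any zero denominator factor is 0.
    """
    if cc.n == 0:
        raise ValueError("empty confusion table")
    recall = cc.TP / (cc.TP + cc.FN) if cc.TP + cc.FN else 0.0
    precision = cc.TP / (cc.TP + cc.FP) if cc.TP + cc.FP else 0.0
    accuracy = (cc.TP + cc.TN) / cc.n
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    denom = (
        (cc.TP + cc.FP) * (cc.TP + cc.FN) * (cc.TN + cc.FP) * (cc.TN + cc.FN)
    )
    mcc = (cc.TP * cc.TN - cc.FP * cc.FN) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(recall, precision, accuracy, f1, mcc)


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts from 0/1 label arrays (1 = circRNA)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass
class TrainedModelBundle:
    """A fitted classifier plus the schema and metadata needed to reuse it."""

    algorithm: str
    hyperparameters: dict
    feature_schema: List[str]
    model: object
    metadata: dict = field(default_factory=dict)


def make_classifier(algorithm: str, seed: int = 0):
    """Unfitted scikit-learn estimator with the package's fixed hyperparameters."""
    if algorithm == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if algorithm == "KNN":
        return KNeighborsClassifier(n_neighbors=7, weights="uniform", p=2)
    if algorithm == "GNB":
        return GaussianNB()
    if algorithm == "SVM":
        return SVC(C=10, gamma=0.001, kernel="rbf", probability=True, random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {list(ALGORITHMS)}")


def _as_matrix(features) -> Tuple[np.ndarray, List[str]]:
    if isinstance(features, pd.DataFrame):
        cols = [c for c in features.columns if c != "label"]
        return features[cols].to_numpy(dtype=float), cols
    X = np.asarray(features, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def _labels_to_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        mapping = {"positive": 1, "negative": 0, POSITIVE_LABEL: 1, NEGATIVE_LABEL: 0}
        try:
            y = np.array([mapping[v] for v in y])
        except KeyError as exc:
            raise ValueError(f"unknown class label {exc.args[0]!r}") from None
    return y.astype(int)


def train_classifier(features, labels, algorithm: str = "RF", seed: int = 0) -> TrainedModelBundle:
    """Fit one of the four classifiers; deterministic given ``seed``.

    ``features`` may be a DataFrame (column names become the schema; a
    ``label`` column is ignored) or a 2-D array.
    """
    X, schema = _as_matrix(features)
    y = _labels_to_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    bad = np.where(~np.isfinite(X))
    if bad[0].size:
        raise ValueError(f"non-finite feature values in column {schema[bad[1][0]]!r}")
    clf = make_classifier(algorithm, seed)
    clf.fit(X, y)
    return TrainedModelBundle(
        algorithm=algorithm,
        hyperparameters=dict(ALGORITHMS[algorithm]),
        feature_schema=list(schema),
        model=clf,
        metadata={
            "seed": seed,
            "date": datetime.now(timezone.utc).isoformat(timespec="seconds"),
            "n_training_records": int(X.shape[0]),
            "dataset_hash": joblib.hash((X, y)),
        },
    )


def predict(bundle: TrainedModelBundle, features) -> pd.DataFrame:
    """Per-record label and circRNA probability score.

    DataFrame input is checked (and re-ordered) against the bundle's feature
    schema; a mismatch raises with the missing/extra column names.
    """
    if isinstance(features, pd.DataFrame):
        cols = [c for c in features.columns if c != "label"]
        missing = [c for c in bundle.feature_schema if c not in cols]
        extra = [c for c in cols if c not in bundle.feature_schema]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch: missing {missing[:5]}, extra {extra[:5]}"
            )
        X = features[bundle.feature_schema].to_numpy(dtype=float)
        index = features.index
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(bundle.feature_schema):
            raise ValueError(
                f"expected {len(bundle.feature_schema)} features, got {X.shape[1]}"
            )
        index = pd.RangeIndex(X.shape[0])
    pos_col = list(bundle.model.classes_).index(1)
    score = bundle.model.predict_proba(X)[:, pos_col]
    label = np.where(score >= 0.5, POSITIVE_LABEL, NEGATIVE_LABEL)
    return pd.DataFrame({"label": label, "score": score}, index=index)


def _mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    aucs = [r.auc for r in reports if r.auc is not None]
    return MetricsReport(
        recall=float(np.mean([r.recall for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        auc=float(np.mean(aucs)) if aucs else None,
    )


def repeated_kfold_cv(
    features,
    labels,
    algorithm: str = "RF",
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> Tuple[MetricsReport, pd.DataFrame]:
    """Repeated stratified k-fold cross-validation.

    Returns the grand-mean report (per-repeat means averaged across repeats)
    and a table with one row per fold: repeat, fold, confusion counts and the
    five metrics plus fold AUC.
    """
    X, _ = _as_matrix(features)
    y = _labels_to_binary(labels)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < k:
        raise ValueError(
            f"smallest class has {class_counts.min()} records; cannot stratify into {k} folds"
        )
    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    rows = []
    fold_reports: List[MetricsReport] = []
    for split_i, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        clf = make_classifier(algorithm, seed)
        clf.fit(X[train_idx], y[train_idx])
        pos_col = list(clf.classes_).index(1)
        score = clf.predict_proba(X[test_idx])[:, pos_col]
        pred = (score >= 0.5).astype(int)
        cc = confusion_from_labels(y[test_idx], pred)
        rep = compute_metrics(cc)
        if len(np.unique(y[test_idx])) == 2:
            rep.auc = float(roc_auc_score(y[test_idx], score))
        fold_reports.append(rep)
        rows.append(
            {
                "repeat": split_i // k,
                "fold": split_i % k,
                "TP": cc.TP,
                "TN": cc.TN,
                "FP": cc.FP,
                "FN": cc.FN,
                **rep.to_dict(),
            }
        )
    table = pd.DataFrame(rows)
    per_repeat = [
        _mean_report(fold_reports[r * k : (r + 1) * k]) for r in range(repeats)
    ]
    return _mean_report(per_repeat), table


def feature_combination_grid(
    feature_table: pd.DataFrame,
    labels,
    blocks: Sequence[str] = ("kmer", "orf", "sjsc"),
    algorithms: Sequence[str] = ("RF",),
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV metrics for every non-empty block combination and algorithm.

    One row per (combination, algorithm) with ACC/PRE/REC/F1/MCC means; 2^n-1
    combinations for n blocks, ordered by size then block order.
    """
    cols_by_block = {b: block_columns(feature_table.columns, b) for b in blocks}
    for b, cols in cols_by_block.items():
        if not cols:
            raise ValueError(f"feature table has no columns for block {b!r}")
    rows = []
    for size in range(1, len(blocks) + 1):
        for combo in combinations(blocks, size):
            cols = [c for b in combo for c in cols_by_block[b]]
            sub = feature_table[cols]
            for algo in algorithms:
                mean, _ = repeated_kfold_cv(sub, labels, algo, k=k, repeats=repeats, seed=seed)
                rows.append(
                    {
                        "combination": "+".join(combo),
                        "n_blocks": size,
                        "algorithm": algo,
                        "ACC": mean.accuracy,
                        "PRE": mean.precision,
                        "REC": mean.recall,
                        "F1": mean.f1,
                        "MCC": mean.mcc,
                    }
                )
    return pd.DataFrame(rows)


def roc_points(y_true, scores) -> List[Tuple[float, float]]:
    """(FPR, TPR) points from a threshold sweep over the unique scores."""
    fpr, tpr, _ = roc_curve(_labels_to_binary(y_true), np.asarray(scores))
    return list(zip(fpr.tolist(), tpr.tolist()))


def pr_points(y_true, scores) -> List[Tuple[float, float]]:
    """(recall, precision) points from a threshold sweep."""
    precision, recall, _ = precision_recall_curve(_labels_to_binary(y_true), np.asarray(scores))
    return list(zip(recall.tolist(), precision.tolist()))


def save_bundle(bundle: TrainedModelBundle, path) -> None:
    joblib.dump(
        {
            "format": _BUNDLE_FORMAT,
            "algorithm": bundle.algorithm,
            "hyperparameters": bundle.hyperparameters,
            "feature_schema": bundle.feature_schema,
            "model": bundle.model,
            "metadata": bundle.metadata,
        },
        path,
    )


def load_bundle(path) -> TrainedModelBundle:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt / truncated file
        raise ValueError(f"cannot load model bundle from {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _BUNDLE_FORMAT:
        raise ValueError(
            f"{path}: not a {_BUNDLE_FORMAT} bundle (got {payload.get('format') if isinstance(payload, dict) else type(payload)})"
        )
    return TrainedModelBundle(
        algorithm=payload["algorithm"],
        hyperparameters=payload["hyperparameters"],
        feature_schema=payload["feature_schema"],
        model=payload["model"],
        metadata=payload["metadata"],
    )
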