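"""Binary-classification metrics and the stratified cross-validation
harness.

Sensitivity, specificity, accuracy and the Matthews correlation
coefficient (MCC) are computed from the confusion counts; MCC is the
primary criterion because SNO datasets are class-imbalanced. Fold
metrics are averaged (mean of per-fold metrics, not pooled confusion) by
default; pooled aggregation is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import knn
from .features import FeatureMatrix

DEFAULT_FOLDS = 10


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """SN, SP, ACC in [0, 1]; MCC in [-1, 1].

    A ratio with a zero denominator is reported as 0 and the metric's
    name recorded in ``undefined`` — poor prefixes in a feature-selection
    sweep should yield a number, not an exception.
    """

    sn: float
    sp: float
    acc: float
    mcc: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"SN": self.sn, "SP": self.sp, "ACC": self.acc, "MCC": self.mcc}


def _safe_ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    undefined: list[str] = []
    sn = _safe_ratio(c.tp, c.tp + c.fn, "SN", undefined)
    sp = _safe_ratio(c.tn, c.tn + c.fp, "SP", undefined)
    acc = _safe_ratio(c.tp + c.tn, c.total, "ACC", undefined)
    den = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = _safe_ratio(c.tp * c.tn - c.fp * c.fn, den, "MCC", undefined)
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc, undefined=tuple(undefined))


def compute_metrics(truth: Sequence[int], predicted: Sequence[int]
                    ) -> tuple[ConfusionCounts, MetricSet]:
    """Confusion counts and metrics for binary label vectors."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError("truth and prediction lengths differ")
    if not (set(np.unique(t)) <= {0, 1} and set(np.unique(p)) <= {0, 1}):
        raise ValueError("labels must be binary 0/1")
    counts = ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )
    return counts, metrics_from_counts(counts)


def make_folds(y: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """One stratified, seeded partition reused by CV and the feature
    search; raises if any training part lacks a class."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    for tr, _ in folds:
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                "a training fold lacks one class; use more samples per class "
                "or fewer folds"
            )
    return folds


@dataclass
class CVResult:
    fold_metrics: list[MetricSet]
    mean: MetricSet
    pooled: MetricSet
    fold_indices: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)


def _mean_metrics(fold_metrics: Sequence[MetricSet]) -> MetricSet:
    return MetricSet(
        sn=float(np.mean([m.sn for m in fold_metrics])),
        sp=float(np.mean([m.sp for m in fold_metrics])),
        acc=float(np.mean([m.acc for m in fold_metrics])),
        mcc=float(np.mean([m.mcc for m in fold_metrics])),
        undefined=tuple(sorted({u for m in fold_metrics for u in m.undefined})),
    )


def cross_validate(
    X: FeatureMatrix,
    feature_subset: Sequence[int] | None = None,
    k_neighbors: int = knn.DEFAULT_K,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV of the KNN rule on a feature subset.

    Each fold standardizes with its own training statistics, fits on the
    training part and predicts the held-out part; the headline result is
    the mean of per-fold metrics.
    """
    if feature_subset is None:
        feature_subset = np.arange(X.n_features)
    subset = np.asarray(feature_subset, dtype=np.int64)
    folds = make_folds(X.y, n_folds, seed)
    fold_metrics: list[MetricSet] = []
    pooled_truth: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for tr, te in folds:
        train = FeatureMatrix(
            X=X.X[np.ix_(tr, subset)], y=X.y[tr],
            feature_names=[X.feature_names[j] for j in subset],
            sample_ids=[X.sample_ids[i] for i in tr],
        )
        model = knn.fit(train, k=k_neighbors)
        pred, _ = knn.predict(model, X.X[np.ix_(te, subset)])
        _, m = compute_metrics(X.y[te], pred)
        fold_metrics.append(m)
        pooled_truth.append(X.y[te])
        pooled_pred.append(pred)
    _, pooled = compute_metrics(np.concatenate(pooled_truth),
                                np.concatenate(pooled_pred))
    return CVResult(fold_metrics=fold_metrics, mean=_mean_metrics(fold_metrics),
                    pooled=pooled, fold_indices=folds)
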