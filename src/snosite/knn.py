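"""k-nearest-neighbor decision rule.

A query site is called an SNO site when the majority of its k nearest
training samples (Euclidean distance, default k = 9) are positive; the
reported score is the positive fraction among those neighbors. Features
are z-score standardized with training-set statistics before distances
are taken, so heterogeneously scaled encoders (integer PSSM sums vs.
composition fractions) contribute comparably.

Determinism: distance ties at the k-th rank are broken by the lower
training-row index; an exact vote tie (possible only for even k) is
resolved to the negative class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureMatrix

DEFAULT_K = 9


@dataclass
class KNNModel:
    """Standardized training data plus the neighbor count."""

    train_matrix: np.ndarray  # (n, d), already standardized
    train_labels: np.ndarray  # (n,) in {0, 1}
    k: int
    mean: np.ndarray  # (d,) training feature means
    std: np.ndarray   # (d,) training feature stds; constants -> 1
    feature_names: list[str]

    def __post_init__(self) -> None:
        n, d = self.train_matrix.shape
        if not (1 <= self.k <= n):
            raise ValueError(f"k={self.k} outside 1..{n} training samples")
        if d < 1:
            raise ValueError("at least one feature required")


def fit(train: FeatureMatrix, k: int = DEFAULT_K) -> KNNModel:
    """Standardize the training matrix and store it with its labels."""
    if k > train.n_samples:
        raise ValueError(f"k={k} exceeds {train.n_samples} training samples")
    mean = train.X.mean(axis=0)
    std = train.X.std(axis=0)
    std[std == 0] = 1.0  # constant features stay at 0 after centering
    Z = (train.X - mean) / std
    return KNNModel(train_matrix=Z, train_labels=train.y.copy(), k=k,
                    mean=mean, std=std, feature_names=list(train.feature_names))


def vote_from_sqdist(d2: np.ndarray, train_labels: np.ndarray, k: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote given a (n_query, n_train) squared-distance matrix.

    Stable argsort implements the lowest-training-index tie-break.
    Returns (labels, positive-neighbor fractions).
    """
    nearest = np.argsort(d2, axis=1, kind="stable")[:, :k]
    scores = train_labels[nearest].mean(axis=1)
    return (scores > 0.5).astype(np.int64), scores


def predict(model: KNNModel, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and scores for query feature vectors (1-D or 2-D array,
    raw scale; the model's standardizer is applied)."""
    Q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    if Q.shape[1] != model.train_matrix.shape[1]:
        raise ValueError(
            f"query has {Q.shape[1]} features, model expects "
            f"{model.train_matrix.shape[1]}"
        )
    Z = (Q - model.mean) / model.std
    d2 = cdist(Z, model.train_matrix, metric="sqeuclidean")
    return vote_from_sqdist(d2, model.train_labels, model.k)


def save_model(model: KNNModel, path: str | Path) -> None:
    """Persist a model as a self-describing JSON archive."""
    payload = {
        "format": "snosite-knn/1",
        "k": model.k,
        "feature_names": model.feature_names,
        "mean": model.mean.tolist(),
        "std": model.std.tolist(),
        "train_matrix": model.train_matrix.tolist(),
        "train_labels": model.train_labels.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> KNNModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "snosite-knn/1":
        raise ValueError(f"{path}: not a snosite KNN model archive")
    return KNNModel(
        train_matrix=np.array(payload["train_matrix"], dtype=np.float64),
        train_labels=np.array(payload["train_labels"], dtype=np.int64),
        k=int(payload["k"]),
        mean=np.array(payload["mean"], dtype=np.float64),
        std=np.array(payload["std"], dtype=np.float64),
        feature_names=list(payload["feature_names"]),
    )
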