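"""Feature ranking by symmetric relative entropy and the incremental
feature selection (IFS) search.

Ranking. For every feature, the class-conditional distributions of its
values among positive and negative samples are estimated by histograms
sharing one set of equal-width bin edges over the pooled range (default
20 bins, Laplace pseudocount 1 per bin, which keeps both divergences
finite). The score is the symmetric Kullback-Leibler divergence
D(P||Q) + D(Q||P) in nats; features are sorted by descending score, ties
broken by ascending original index.

IFS. Growing prefixes of the ranked list are evaluated by stratified
k-fold cross-validation of the KNN rule — one shared fold partition for
every prefix size, so the curve reflects feature-set changes only — and
the prefix with the maximum mean MCC (smallest size among ties) is the
optimal subset. Squared Euclidean distances are updated incrementally as
each ranked feature column is appended, which makes the full sweep over
all prefix sizes cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import knn, metrics
from .features import FeatureMatrix

DEFAULT_BINS = 20
DEFAULT_PSEUDOCOUNT = 1.0


def symmetric_kl(
    pos_values: Sequence[float],
    neg_values: Sequence[float],
    bins: int = DEFAULT_BINS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Symmetric KL divergence between the two class-conditional
    histograms of one feature, in nats.

    Both samples are binned on shared equal-width edges spanning the
    pooled min-max range; ``pseudocount`` is added to every bin before
    normalization. A feature constant across both classes scores 0.
    With ``pseudocount=0``, empty-bin terms follow the usual KL
    conventions (0*log(0/q) = 0; p>0 against q=0 gives inf).
    """
    p_vals = np.asarray(pos_values, dtype=np.float64)
    q_vals = np.asarray(neg_values, dtype=np.float64)
    if p_vals.size == 0 or q_vals.size == 0:
        raise ValueError("both class samples must be non-empty")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    lo = min(p_vals.min(), q_vals.min())
    hi = max(p_vals.max(), q_vals.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p_counts = np.histogram(p_vals, bins=edges)[0].astype(np.float64) + pseudocount
    q_counts = np.histogram(q_vals, bins=edges)[0].astype(np.float64) + pseudocount
    p = p_counts / p_counts.sum()
    q = q_counts / q_counts.sum()
    return float(_kl(p, q) + _kl(q, p))


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    with np.errstate(divide="ignore"):
        terms = p[mask] * np.log(p[mask] / q[mask])
    return float(terms.sum())


@dataclass
class RankedFeatureList:
    """Feature indices in descending symmetric-KL order."""

    order: np.ndarray   # permutation of feature indices
    scores: np.ndarray  # score per feature, in original index order
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.order.shape != self.scores.shape:
            raise ValueError("order and scores must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.order) + 1),
            "feature_index": self.order,
            "feature_name": [self.feature_names[i] for i in self.order],
            "score": self.scores[self.order],
        })


def rank_features(X: FeatureMatrix, bins: int = DEFAULT_BINS,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT) -> RankedFeatureList:
    """Score every feature and sort descending (ties: lower index first)."""
    if len(np.unique(X.y)) < 2:
        raise ValueError("feature ranking requires samples of both classes")
    pos = X.X[X.y == 1]
    neg = X.X[X.y == 0]
    scores = np.array([
        symmetric_kl(pos[:, j], neg[:, j], bins=bins, pseudocount=pseudocount)
        for j in range(X.n_features)
    ])
    order = np.lexsort((np.arange(X.n_features), -scores))
    return RankedFeatureList(order=order, scores=scores,
                             feature_names=list(X.feature_names))


@dataclass
class IFSTable:
    """Mean cross-validated metrics per ranked-prefix size."""

    table: pd.DataFrame  # columns: size, SN, SP, ACC, MCC
    optimal_size: int
    order: np.ndarray

    @property
    def optimal_subset(self) -> np.ndarray:
        return self.order[: self.optimal_size]


def ifs_search(
    X: FeatureMatrix,
    ranked: RankedFeatureList,
    k_neighbors: int = knn.DEFAULT_K,
    n_folds: int = metrics.DEFAULT_FOLDS,
    seed: int = 0,
    max_size: int | None = None,
) -> IFSTable:
    """Evaluate every prefix of the ranked list under one shared CV
    partition and locate the MCC-optimal prefix.

    ``max_size`` truncates the sweep (default: all features).
    """
    order = ranked.order
    if max_size is not None:
        order = order[:max_size]
    n_prefix = len(order)
    folds = metrics.make_folds(X.y, n_folds, seed)

    # per fold: standardize the rank-ordered columns with training stats,
    # then grow the squared-distance matrix one column at a time
    fold_state = []
    for tr, te in folds:
        Xtr = X.X[np.ix_(tr, order)]
        Xte = X.X[np.ix_(te, order)]
        mean = Xtr.mean(axis=0)
        std = Xtr.std(axis=0)
        std[std == 0] = 1.0
        Ztr = (Xtr - mean) / std
        Zte = (Xte - mean) / std
        d2 = np.zeros((len(te), len(tr)))
        fold_state.append((Ztr, Zte, X.y[tr], X.y[te], d2))

    rows = []
    for step in range(n_prefix):
        fold_metrics = []
        for Ztr, Zte, ytr, yte, d2 in fold_state:
            diff = Zte[:, step][:, None] - Ztr[None, :, step]
            d2 += diff * diff
            pred, _ = knn.vote_from_sqdist(d2, ytr, k_neighbors)
            _, m = metrics.compute_metrics(yte, pred)
            fold_metrics.append(m)
        mean = metrics._mean_metrics(fold_metrics)
        rows.append((step + 1, mean.sn, mean.sp, mean.acc, mean.mcc))

    table = pd.DataFrame(rows, columns=["size", "SN", "SP", "ACC", "MCC"])
    mccs = table["MCC"].to_numpy()
    optimal_size = int(np.argmax(mccs) + 1)  # argmax takes the first max: smallest size
    return IFSTable(table=table, optimal_size=optimal_size, order=order.copy())
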