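"""k-means partitioning and re-clustering of occupancy profiles.

Profiles from one or more row-aligned signal matrices are concatenated and
clustered with Euclidean k-means.  Rows are z-scored per row by default so
the partition reflects profile shape rather than amplitude; amplitude is
recovered by relabelling clusters in descending mean original-scale signal,
which makes cluster labels stable in meaning across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .matrices import SignalMatrix

__all__ = [
    "ProfileKMeans",
    "ClusterAssignment",
    "kmeans_profiles",
    "recluster",
    "match_labels",
    "label_agreement",
]


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


class ProfileKMeans(BaseEstimator, ClusterMixin):
    """Euclidean k-means over profile rows, sklearn estimator style.

    Parameters
    ----------
    n_clusters : number of clusters k (k >= 1, k <= n rows).
    zscore_rows : z-score each row before clustering (shape over amplitude).
    n_init, max_iter : passed to k-means (k-means++ init, best of restarts).
    random_state : seed; identical inputs and seed give identical output.

    Fitted attributes
    -----------------
    labels_ : cluster label per row, relabelled in descending mean
        original-scale row signal.
    cluster_centers_ : per-cluster mean profile in the clustering space.
    mean_signal_ : per-cluster mean of the original rows.
    inertia_ : within-cluster sum of squares of the best restart.
    """

    def __init__(self, n_clusters: int = 6, zscore_rows: bool = True,
                 n_init: int = 10, max_iter: int = 300,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.zscore_rows = zscore_rows
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (rows are profiles)")
        if not np.all(np.isfinite(X)):
            raise ValueError("profiles contain NaN or infinite values")
        if not 1 <= self.n_clusters <= X.shape[0]:
            raise ValueError(
                f"n_clusters={self.n_clusters} outside [1, {X.shape[0]}]"
            )
        Z = _zscore_rows(X) if self.zscore_rows else X
        km = KMeans(
            n_clusters=self.n_clusters, init="k-means++", n_init=self.n_init,
            max_iter=self.max_iter, random_state=self.random_state,
        ).fit(Z)
        raw_labels = km.labels_
        # canonical relabelling: descending mean original-scale signal,
        # ties broken by original label index
        means = np.array([
            X[raw_labels == c].mean() if np.any(raw_labels == c) else -np.inf
            for c in range(self.n_clusters)
        ])
        order = np.argsort(-means, kind="stable")
        remap = np.empty(self.n_clusters, dtype=int)
        remap[order] = np.arange(self.n_clusters)
        self.labels_ = remap[raw_labels]
        self.cluster_centers_ = km.cluster_centers_[order]
        self.mean_signal_ = means[order]
        self.inertia_ = float(km.inertia_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass(frozen=True)
class ClusterAssignment:
    """Anchor id -> cluster label, plus centroids and provenance."""

    anchor_ids: tuple[str, ...]
    labels: np.ndarray
    k: int
    centroids: np.ndarray  # k x n_features, clustering space
    seed: int
    inertia: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if len(labels) != len(self.anchor_ids):
            raise ValueError("one label per anchor required")
        if labels.size and (labels.min() < 0 or labels.max() >= self.k):
            raise ValueError("labels must lie in [0, k)")

    def members(self, label: int) -> list[str]:
        return [a for a, l in zip(self.anchor_ids, self.labels) if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"anchor_id": list(self.anchor_ids), "cluster": self.labels}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _stack(matrices) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(matrices, SignalMatrix):
        matrices = [matrices]
    if not matrices:
        raise ValueError("at least one matrix required")
    ids = matrices[0].anchor_ids
    for m in matrices[1:]:
        if m.anchor_ids != ids:
            raise ValueError("matrices must be row-aligned over the same anchors")
    return np.hstack([m.values for m in matrices]), ids


def kmeans_profiles(
    matrices, k: int, seed: int = 0, zscore_rows: bool = True
) -> ClusterAssignment:
    """Cluster concatenated profile rows from row-aligned matrices."""
    X, ids = _stack(matrices)
    est = ProfileKMeans(n_clusters=k, zscore_rows=zscore_rows,
                        random_state=seed).fit(X)
    return ClusterAssignment(ids, est.labels_, k, est.cluster_centers_,
                             seed, est.inertia_)


def recluster(
    assignment: ClusterAssignment,
    labels_subset,
    matrices,
    k2: int,
    seed: int = 0,
    zscore_rows: bool = True,
) -> ClusterAssignment:
    """k-means restricted to the members of the given cluster labels."""
    subset = set(labels_subset)
    missing = subset - set(range(assignment.k))
    if missing:
        raise ValueError(f"labels not in assignment: {sorted(missing)}")
    X, ids = _stack(matrices)
    if ids != assignment.anchor_ids:
        raise ValueError("matrices not aligned with the assignment")
    mask = np.isin(assignment.labels, sorted(subset))
    if not mask.any():
        raise ValueError("selected clusters are empty")
    est = ProfileKMeans(n_clusters=k2, zscore_rows=zscore_rows,
                        random_state=seed).fit(X[mask])
    sub_ids = tuple(np.asarray(ids)[mask])
    return ClusterAssignment(sub_ids, est.labels_, k2, est.cluster_centers_,
                             seed, est.inertia_)


def match_labels(true_labels, pred_labels) -> dict[int, int]:
    """Optimal predicted->true label map (Hungarian on the confusion matrix)."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    t_vals = np.unique(true_labels)
    p_vals = np.unique(pred_labels)
    conf = np.zeros((len(p_vals), len(t_vals)))
    for i, p in enumerate(p_vals):
        for j, t in enumerate(t_vals):
            conf[i, j] = np.sum((pred_labels == p) & (true_labels == t))
    rows, cols = linear_sum_assignment(-conf)
    return {int(p_vals[r]): int(t_vals[c]) for r, c in zip(rows, cols)}


def label_agreement(true_labels, pred_labels) -> float:
    """Fraction of rows agreeing with truth after optimal label matching."""
    mapping = match_labels(true_labels, pred_labels)
    pred_mapped = np.array([mapping.get(int(p), -1) for p in pred_labels])
    return float(np.mean(pred_mapped == np.asarray(true_labels)))
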