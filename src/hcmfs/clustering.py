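"""Ward agglomerative clustering of features (not samples).

Each feature is viewed as a z-scored column vector over the samples and
features are merged under Euclidean distance with Ward's minimum-variance
criterion.  For standardized columns the squared Euclidean distance is a
monotone function of the Pearson correlation (d^2 = 2n(1 - r)), so tightly
co-varying features merge early and weakly related ones late.  Cutting the
tree at k classes yields the feature partition consumed by the HC-MFS
selector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .cohort import FeatureTable

_STD_TOL = 1e-6


@dataclass(frozen=True)
class Dendrogram:
    """Ordered Ward merge history over features.

    ``merges`` follows the usual linkage convention: entry i merges nodes
    ``a`` and ``b`` (leaves are 0..n-1, internal nodes n+i) at ``height``
    into a cluster of ``size`` leaves.
    """

    merges: tuple[tuple[int, int, float, int], ...]
    leaf_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaf_names) - 1:
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def to_linkage(self) -> np.ndarray:
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    @classmethod
    def from_linkage(cls, Z: np.ndarray, leaf_names) -> "Dendrogram":
        merges = tuple(
            (int(a), int(b), float(h), int(s)) for a, b, h, s in np.asarray(Z)
        )
        return cls(merges, tuple(leaf_names))


@dataclass(frozen=True)
class FeatureClassAssignment:
    """Partition of features into classes 1..k (ids contiguous, ordered by
    first-appearing leaf)."""

    classes: dict[str, int]
    k: int

    def members(self, class_id: int) -> list[str]:
        return [f for f, c in self.classes.items() if c == class_id]

    def as_partition(self) -> list[frozenset]:
        return [frozenset(self.members(c)) for c in range(1, self.k + 1)]


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = np.zeros_like(X)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    return out


def feature_distance_matrix(table: FeatureTable) -> tuple[np.ndarray, list[str]]:
    """Euclidean distances between z-scored feature columns.

    Non-standardized input triggers a warning and internal standardization
    (all columns, categorical codes included, are z-scored for the feature
    geometry).  Returns the symmetric matrix and the feature-name order.
    """
    table.require_complete("feature_distance_matrix")
    X = table.values.to_numpy(dtype=float)
    num = np.array([table.meta[c].kind == "numeric" for c in table.feature_names])
    if num.any():
        mu = X[:, num].mean(axis=0)
        sd = X[:, num].std(axis=0)
        if np.abs(mu).max() > _STD_TOL or np.abs(sd[sd > 0] - 1.0).max(initial=0.0) > _STD_TOL:
            warnings.warn(
                "numeric feature columns are not standardized; z-scoring internally",
                stacklevel=2,
            )
    X = _zscore_columns(X)
    D = squareform(pdist(X.T, metric="euclidean"))
    return D, table.feature_names


def ward_cluster(dist: np.ndarray, leaf_names=None) -> Dendrogram:
    """Ward agglomeration over a feature distance matrix.

    Merge heights are the usual Ward/Lance-Williams cluster distances and
    are non-decreasing.  Deterministic for distinct merge costs.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two features to cluster")
    if leaf_names is None:
        leaf_names = [f"f{i}" for i in range(n)]
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    return Dendrogram.from_linkage(Z, leaf_names)


def cut_tree(dendro: Dendrogram, k: int) -> FeatureClassAssignment:
    """Cut the dendrogram into exactly k classes by removing the k-1 highest
    merges; class ids are renumbered 1..k by first-appearing leaf."""
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    raw = hierarchy.fcluster(dendro.to_linkage(), t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for c in raw:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    classes = {name: relabel[c] for name, c in zip(dendro.leaf_names, raw)}
    return FeatureClassAssignment(classes, k=len(relabel))


def cluster_features(table: FeatureTable, k: int = 3) -> tuple[Dendrogram, FeatureClassAssignment]:
    """Convenience: distance matrix -> Ward tree -> k-class cut."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        D, names = feature_distance_matrix(table)
    dendro = ward_cluster(D, names)
    return dendro, cut_tree(dendro, k)


def suggest_k(table: FeatureTable, k_range=range(2, 7)) -> int:
    """Silhouette-based suggestion for the number of feature classes.

    Advisory only: an explicitly configured k always wins.
    """
    from sklearn.metrics import silhouette_score

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        D, names = feature_distance_matrix(table)
    dendro = ward_cluster(D, names)
    best_k, best_s = None, -np.inf
    for k in k_range:
        if not 2 <= k <= len(names) - 1:
            continue
        labels = [cut_tree(dendro, k).classes[n] for n in names]
        s = silhouette_score(D, labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no admissible k in range")
    return best_k


def plot_dendrogram(dendro: Dendrogram, path) -> None:
    """Render the feature dendrogram to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, dendro.n_leaves * 0.5), 4))
    hierarchy.dendrogram(dendro.to_linkage(), labels=list(dendro.leaf_names), ax=ax)
    ax.set_ylabel("Ward merge height")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
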