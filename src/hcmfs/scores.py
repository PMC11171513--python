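"""Feature-relevance measures for a binary outcome.

Four filter scores are provided:

* **Fisher score** -- ratio of between-class to within-class scatter,
  ``sum_c n_c (mu_c - mu)^2 / sum_c n_c sigma_c^2`` with population
  (1/n_c) class variances.  Scale- and translation-invariant.
* **Relief-F** -- instance-based weighting: for each sampled instance the
  feature weight rises with its separation from the k nearest misses
  (other class) and falls with separation from the k nearest hits (same
  class), differences range-normalized to [0, 1].
* **Mutual information** -- plug-in estimate in nats on the discretized
  joint distribution; numeric features are cut into equal-frequency bins.
* **Distance correlation** -- Szekely's dCor in [0, 1], from
  double-centered pairwise-distance matrices; zero (population version)
  iff independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import NUMERIC, FeatureTable

METHODS = ("FS", "R_F", "MI", "DCFS")


@dataclass(frozen=True)
class ScoreVector:
    """Per-feature relevance scores for one method, in column order."""

    method: str
    scores: dict[str, float]
    params: dict = field(default_factory=dict)

    def ranking(self) -> list[str]:
        """Feature names by descending score; ties keep column order."""
        names = list(self.scores)
        return sorted(names, key=lambda n: (-self.scores[n], names.index(n)))

    def top_k(self, k: int) -> list[str]:
        if not 1 <= k <= len(self.scores):
            raise ValueError(f"k={k} outside 1..{len(self.scores)}")
        return self.ranking()[:k]


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.size == 0:
        raise ValueError("empty input")
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y length mismatch")
    return x, y


def fisher_score(x, y) -> float:
    """Fisher score of one feature against binary labels (>= 0)."""
    x, y = _check_xy(x, y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be non-empty")
    mu = x.mean()
    num = 0.0
    den = 0.0
    for c in classes:
        xc = x[y == c]
        num += xc.size * (xc.mean() - mu) ** 2
        den += xc.size * xc.var()  # population variance
    if den == 0:
        if num == 0:
            return 0.0
        raise ValueError("zero within-class variance with separated class means")
    return float(num / den)


def mutual_information(x, y, bins: int = 10) -> float:
    """Plug-in mutual information (nats) between x and binary labels.

    Numeric x is discretized into ``bins`` equal-frequency bins (duplicate
    bin edges collapsed); x with few distinct values is used as-is.
    """
    x, y = _check_xy(x, y)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    xs = np.unique(x)
    if xs.size > bins:
        edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)))
        codes = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)
    else:
        codes = np.searchsorted(xs, x)
    joint = np.zeros((codes.max() + 1, 2))
    ycode = (y == np.unique(y)[-1]).astype(int) if np.unique(y).size == 2 else y.astype(int)
    np.add.at(joint, (codes, ycode), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log(joint / (px * py))
    return float(max(np.nansum(term), 0.0))


def distance_correlation(x, y) -> float:
    """Szekely's distance correlation between two numeric vectors, in [0, 1].

    Uses the biased sample dCor: double-center each pairwise-distance matrix,
    then dCor = dCov / sqrt(dVar_x * dVar_y); returns 0 when either dVar is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y length mismatch")
    if x.shape[0] < 2:
        raise ValueError("need n >= 2")

    def centered(v):
        d = np.abs(v[:, None] - v[None, :])
        return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()

    ax, ay = centered(x), centered(y)
    dcov2 = (ax * ay).mean()
    dvarx = (ax * ax).mean()
    dvary = (ay * ay).mean()
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)))


def relief_f(
    table: FeatureTable, k: int = 10, m: int | None = None, seed: int = 0
) -> ScoreVector:
    """Relief-F feature weights for a two-class table.

    ``m`` instances are sampled (default: all, in order); for each, the k
    nearest hits and k nearest misses (Manhattan distance on the
    range-normalized features) update every feature's weight by
    (miss diffs - hit diffs), finally divided by m*k.  Numeric diffs are
    |a-b|/range; categorical/binary diffs are 0/1 indicators.
    """
    table.require_complete("relief_f")
    y = table.labels.to_numpy()
    n = y.size
    counts = np.bincount(y.astype(int), minlength=2)
    if k < 1 or k > counts.min() - 1:
        raise ValueError(f"k={k} exceeds smallest class size - 1 ({counts.min() - 1})")
    names = table.feature_names
    X = table.values.to_numpy(dtype=float)
    numeric = np.array([table.meta[c].kind == NUMERIC for c in names])
    D = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if numeric[j]:
            rng_ = col.max() - col.min()
            D[:, j] = (col - col.min()) / rng_ if rng_ > 0 else 0.0
        else:
            D[:, j] = col

    if m is None or m >= n:
        idx = np.arange(n)
    else:
        idx = np.sort(np.random.default_rng(seed).choice(n, size=m, replace=False))

    weights = np.zeros(X.shape[1])
    for i in idx:
        diffs = np.abs(D - D[i])  # n x p
        if not numeric.all():
            diffs[:, ~numeric] = (diffs[:, ~numeric] != 0).astype(float)
        dist = diffs.sum(axis=1)
        same = y == y[i]
        hit_pool = np.flatnonzero(same)
        hit_pool = hit_pool[hit_pool != i]
        miss_pool = np.flatnonzero(~same)
        hits = hit_pool[np.argsort(dist[hit_pool], kind="stable")[:k]]
        misses = miss_pool[np.argsort(dist[miss_pool], kind="stable")[:k]]
        weights += diffs[misses].sum(axis=0) - diffs[hits].sum(axis=0)
    weights /= len(idx) * k
    return ScoreVector("R_F", dict(zip(names, weights.tolist())), {"k": k, "m": len(idx), "seed": seed})


def rank_features(table: FeatureTable, method: str, **params) -> ScoreVector:
    """Score every feature with one method and return a ranked ScoreVector.

    Ties in the ranking are broken by original column order.
    """
    table.require_complete("rank_features")
    y = table.labels.to_numpy()
    if method == "R_F":
        return relief_f(table, **params)
    scores: dict[str, float] = {}
    for name in table.feature_names:
        x = table.values[name].to_numpy(dtype=float)
        if method == "FS":
            scores[name] = fisher_score(x, y)
        elif method == "MI":
            scores[name] = mutual_information(x, y, bins=params.get("bins", 10))
        elif method == "DCFS":
            scores[name] = distance_correlation(x, y.astype(float))
        else:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return ScoreVector(method, scores, dict(params))
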