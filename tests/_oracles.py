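"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: Ward
agglomeration is recomputed from cluster centroids at every step, distance
correlation is evaluated with explicit O(n^2) loops, and the greedy wrapper
search is replayed candidate by candidate with direct scikit-learn calls.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import clone


def naive_ward_merges(points: np.ndarray):
    """Agglomerate by recomputing every pairwise Ward cost from scratch.

    Returns the merge history as (frozenset_a, frozenset_b, height) with the
    conventional height sqrt(2 * cost) for Euclidean Ward linkage.
    """
    clusters: list[set[int]] = [{i} for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                ca = points[list(a)].mean(axis=0)
                cb = points[list(b)].mean(axis=0)
                cost = (len(a) * len(b)) / (len(a) + len(b)) * float(((ca - cb) ** 2).sum())
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        cost, i, j = best
        a, b = clusters[i], clusters[j]
        merges.append((frozenset(a), frozenset(b), math.sqrt(2.0 * cost)))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(a | b)
    return merges


def dendrogram_merge_sets(dendro):
    """Library merge history in the same (set_a, set_b, height) form."""
    n = dendro.n_leaves
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, h, _) in enumerate(dendro.merges):
        sa, sb = members[a], members[b]
        out.append((sa, sb, h))
        members[n + step] = sa | sb
    return out


def naive_distance_correlation(x, y) -> float:
    """Double-centering dCor with explicit loops."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)

    def center(v):
        d = [[abs(v[i] - v[j]) for j in range(n)] for i in range(n)]
        row = [sum(d[i]) / n for i in range(n)]
        col = [sum(d[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[d[i][j] - row[i] - col[j] + grand for j in range(n)] for i in range(n)]

    ax, ay = center(x), center(y)
    dcov2 = sum(ax[i][j] * ay[i][j] for i in range(n) for j in range(n)) / n**2
    dvx = sum(ax[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    dvy = sum(ay[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return math.sqrt(max(dcov2, 0.0) / math.sqrt(dvx * dvy))


def replay_forward_search(table, seed_subset, candidates, estimator, folds_idx):
    """Step-by-step exhaustive re-evaluation of the greedy forward rule.

    Visits ``candidates`` in order, recomputing every CV accuracy with
    direct scikit-learn fits, and accepts a candidate iff it strictly
    improves on the current subset's accuracy.
    """
    y = table.labels.to_numpy()

    def cv_acc(cols):
        if not cols:
            accs = []
            for tr, te in folds_idx:
                maj = np.bincount(y[tr].astype(int)).argmax()
                accs.append((y[te] == maj).mean())
            return float(np.mean(accs))
        X = table.values[list(cols)].to_numpy(dtype=float)
        accs = []
        for tr, te in folds_idx:
            est = clone(estimator)
            est.fit(X[tr], y[tr])
            accs.append((est.predict(X[te]) == y[te]).mean())
        return float(np.mean(accs))

    current = list(seed_subset)
    acc = cv_acc(current)
    for cand in candidates:
        trial = cv_acc(current + [cand])
        if trial > acc:
            current, acc = current + [cand], trial
    return current, acc
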