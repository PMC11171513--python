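"""HC-MFS: dual feature selection by feature clustering and mean Fisher score.

The selector combines a redundancy view (Ward clustering of features) with a
relevance view (Fisher scores) and then refines the seed subset with greedy
wrapper searches:

1. **Cluster** the features into k classes with Ward agglomeration.
2. **Score** every feature with the Fisher score and compute each class's
   mean Fisher score (MFS).
3. **Seed**: features whose Fisher score strictly exceeds their class MFS
   form the initial subset F_FSS -- the locally most discriminative
   representative(s) of each feature cluster.
4. **Search**: a forward pass adds remaining features (one visit each, in
   descending Fisher order) when they strictly improve cross-validated
   accuracy; a backward pass starts from the full feature set and removes
   non-seed features (ascending Fisher order) when removal does not hurt.
   The fold partition is frozen once per search so comparisons are paired.
5. **Compare**: the direction with the higher final accuracy wins; on a tie
   the smaller subset wins, and on a full tie the forward result is kept.

Seed features are never removed by the backward pass, so the seed's
relevance floor is preserved in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bench import ModelConfig, fold_indices, mean_cv_accuracy
from .clustering import FeatureClassAssignment, cluster_features
from .cohort import FeatureTable
from .scores import ScoreVector, rank_features


@dataclass(frozen=True)
class HcmfsConfig:
    """Settings for one HC-MFS run."""

    k_classes: int = 3
    model: ModelConfig = field(default_factory=lambda: ModelConfig("LR", {"solver": "liblinear"}, "IMV+SS"))
    cv_folds: int = 5
    seed: int = 0
    candidate_order: str = "fisher_desc"

    def __post_init__(self) -> None:
        if self.k_classes < 1:
            raise ValueError("k_classes must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.candidate_order != "fisher_desc":
            raise ValueError(f"unknown candidate order {self.candidate_order!r}")


@dataclass(frozen=True)
class InitialSubset:
    """Seed subset F_FSS with the per-class mean Fisher scores behind it."""

    features: tuple[str, ...]
    class_means: dict[int, float]
    fisher_scores: ScoreVector


@dataclass
class SelectionResult:
    """Outcome of one wrapper search (or of the full HC-MFS pipeline)."""

    subset: list[str]
    direction: str  # "forward" | "backward"
    accuracy_trace: list[tuple[int, float]]
    final_accuracy: float
    meta: dict = field(default_factory=dict)


def mean_fisher_by_class(
    scores: ScoreVector, classes: FeatureClassAssignment
) -> dict[int, float]:
    """Arithmetic mean of the Fisher scores within each feature class."""
    missing = [f for f in classes.classes if f not in scores.scores]
    if missing:
        raise KeyError(f"features without a Fisher score: {missing}")
    means: dict[int, float] = {}
    for cid in range(1, classes.k + 1):
        members = classes.members(cid)
        means[cid] = sum(scores.scores[f] for f in members) / len(members)
    return means


def initial_subset(
    scores: ScoreVector, classes: FeatureClassAssignment
) -> InitialSubset:
    """Features whose Fisher score strictly exceeds their class mean.

    A class of tied scores contributes nothing (strict inequality); a
    singleton class likewise, since its only score equals the class mean.
    """
    means = mean_fisher_by_class(scores, classes)
    chosen = tuple(
        f for f, cid in classes.classes.items() if scores.scores[f] > means[cid]
    )
    return InitialSubset(chosen, means, scores)


def _search(
    table: FeatureTable,
    seed_subset,
    config: HcmfsConfig,
    direction: str,
    fisher: ScoreVector | None = None,
) -> SelectionResult:
    table.require_complete("wrapper search")
    if not table.feature_names:
        raise ValueError("empty feature set")
    seed_subset = list(seed_subset)
    unknown = set(seed_subset) - set(table.feature_names)
    if unknown:
        raise KeyError(f"seed features not in table: {sorted(unknown)}")
    fisher = fisher or rank_features(table, "FS")
    order = fisher.ranking()
    candidates = [f for f in order if f not in seed_subset]
    if direction == "backward":
        candidates = candidates[::-1]  # ascending Fisher score

    folds_idx = fold_indices(table.labels.to_numpy(), config.cv_folds, config.seed)
    est = config.model.build()
    scale = config.model.scale_in_fold

    def acc(subset) -> float:
        return mean_cv_accuracy(table, subset, est, folds_idx, scale)

    decisions = []
    if direction == "forward":
        current = list(seed_subset)
        current_acc = acc(current)
        trace = [(len(current), current_acc)]
        for cand in candidates:
            trial_acc = acc(current + [cand])
            accept = trial_acc > current_acc  # strict improvement required
            decisions.append((cand, trial_acc, accept))
            if accept:
                current = current + [cand]
                current_acc = trial_acc
                trace.append((len(current), current_acc))
    else:
        current = [f for f in order]  # full set, descending Fisher order
        current_acc = acc(current)
        trace = [(len(current), current_acc)]
        for cand in candidates:
            trial = [f for f in current if f != cand]
            trial_acc = acc(trial)
            accept = trial_acc >= current_acc  # removal must not hurt
            decisions.append((cand, trial_acc, accept))
            if accept:
                current = trial
                current_acc = trial_acc
                trace.append((len(current), current_acc))
    return SelectionResult(
        subset=current,
        direction=direction,
        accuracy_trace=trace,
        final_accuracy=max(a for _, a in trace),
        meta={"decisions": decisions, "seed_subset": seed_subset},
    )


def forward_search(table: FeatureTable, seed_subset, config: HcmfsConfig) -> SelectionResult:
    """Grow F_FSS greedily: each outside candidate is visited once in
    descending Fisher order and kept iff it strictly increases CV accuracy."""
    return _search(table, seed_subset, config, "forward")


def backward_search(table: FeatureTable, seed_subset, config: HcmfsConfig) -> SelectionResult:
    """Shrink the full feature set greedily: each non-seed feature is visited
    once in ascending Fisher order and dropped iff removal does not decrease
    CV accuracy.  Seed features are never removed."""
    return _search(table, seed_subset, config, "backward")


def _choose(forward: SelectionResult, backward: SelectionResult) -> SelectionResult:
    """Step-5 rule: higher accuracy wins; tie -> fewer features; full tie ->
    forward."""
    if forward.final_accuracy != backward.final_accuracy:
        return forward if forward.final_accuracy > backward.final_accuracy else backward
    if len(forward.subset) != len(backward.subset):
        return forward if len(forward.subset) < len(backward.subset) else backward
    return forward


def hc_mfs_select(table: FeatureTable, config: HcmfsConfig | None = None) -> SelectionResult:
    """Run the full HC-MFS pipeline on a preprocessed table."""
    config = config or HcmfsConfig()
    _, classes = cluster_features(table, k=config.k_classes)
    fisher = rank_features(table, "FS")
    seed = initial_subset(fisher, classes)
    fwd = _search(table, seed.features, config, "forward", fisher)
    bwd = _search(table, seed.features, config, "backward", fisher)
    winner = _choose(fwd, bwd)
    winner.meta.update(
        {
            "initial_subset": list(seed.features),
            "class_means": seed.class_means,
            "forward_accuracy": fwd.final_accuracy,
            "backward_accuracy": bwd.final_accuracy,
            "forward_size": len(fwd.subset),
            "backward_size": len(bwd.subset),
        }
    )
    return winner
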