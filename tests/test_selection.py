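import numpy as np
import pytest

from _util import make_numeric_table
from hcmfs import (
    HcmfsConfig,
    ModelConfig,
    ScoreVector,
    backward_search,
    forward_search,
    hc_mfs_select,
    initial_subset,
    mean_fisher_by_class,
)
from hcmfs.bench import fold_indices, mean_cv_accuracy
from hcmfs.clustering import FeatureClassAssignment
from hcmfs.selection import _choose, SelectionResult

KNN1 = ModelConfig("KNN", {"n_neighbors": 1}, "IMV")
LR_CFG = ModelConfig("LR", {}, "IMV")


def sv(scores):
    return ScoreVector("FS", scores)


class TestMeanFisherByClass:
    def test_arithmetic_mean_per_class(self):
        classes = FeatureClassAssignment({"a": 1, "b": 1, "c": 2}, k=2)
        means = mean_fisher_by_class(sv({"a": 0.5, "b": 0.1, "c": 0.7}), classes)
        assert means == {1: pytest.approx(0.3), 2: pytest.approx(0.7)}

    def test_singleton_class_mean_is_its_score(self):
        classes = FeatureClassAssignment({"a": 1}, k=1)
        assert mean_fisher_by_class(sv({"a": 0.42}), classes) == {1: 0.42}

    def test_missing_score_is_error(self):
        classes = FeatureClassAssignment({"a": 1, "b": 1}, k=1)
        with pytest.raises(KeyError, match="b"):
            mean_fisher_by_class(sv({"a": 0.5}), classes)


class TestInitialSubset:
    def test_strict_threshold_excludes_ties(self):
        classes = FeatureClassAssignment({"a": 1, "b": 1, "c": 2, "d": 2}, k=2)
        seed = initial_subset(sv({"a": 0.5, "b": 0.1, "c": 0.3, "d": 0.3}), classes)
        assert set(seed.features) == {"a"}  # class 2 all tied -> nothing seeded

    def test_global_mean_with_single_class(self):
        classes = FeatureClassAssignment({"a": 1, "b": 1, "c": 1, "d": 1}, k=1)
        seed = initial_subset(sv({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}), classes)
        assert set(seed.features) == {"c", "d"}  # strictly above mean 2.5

    def test_can_seed_eight_of_twenty(self, planted_table):
        """The seeding rule can return a mid-sized subset from 20 features."""
        from hcmfs import cluster_features, rank_features
        from hcmfs.preprocess import standardize

        _, classes = cluster_features(standardize(planted_table), k=3)
        seed = initial_subset(rank_features(planted_table, "FS"), classes)
        assert 1 <= len(seed.features) < 20


@pytest.fixture
def redundant_table():
    """f0 separates the classes; f1 duplicates f0; f2 is noise."""
    rng = np.random.default_rng(2)
    y = np.repeat([0, 1], 25)
    f0 = y + 0.1 * rng.standard_normal(50)
    return make_numeric_table(np.column_stack([f0, f0, rng.standard_normal(50)]), y)


class TestForwardSearch:
    def test_duplicate_candidate_rejected(self, redundant_table):
        cfg = HcmfsConfig(model=KNN1, seed=0)
        res = forward_search(redundant_table, ["f0"], cfg)
        assert "f1" not in res.subset  # no accuracy gain over its duplicate

    def test_final_accuracy_never_below_seed(self, redundant_table):
        cfg = HcmfsConfig(model=KNN1, seed=0)
        res = forward_search(redundant_table, ["f0"], cfg)
        folds = fold_indices(redundant_table.labels.to_numpy(), 5, 0)
        seed_acc = mean_cv_accuracy(redundant_table, ["f0"], KNN1.build(), folds)
        assert res.final_accuracy >= seed_acc
        assert res.final_accuracy == max(a for _, a in res.accuracy_trace)

    def test_every_candidate_visited_once(self, planted_table):
        cfg = HcmfsConfig(model=LR_CFG, seed=1)
        seed = ["signal_01", "signal_02"]
        res = forward_search(planted_table, seed, cfg)
        visited = [c for c, _, _ in res.meta["decisions"]]
        assert sorted(visited) == sorted(set(planted_table.feature_names) - set(seed))

    def test_noise_candidates_mostly_rejected(self):
        """One useful + four pure-noise candidates around a strong seed: the
        noise is rejected (at most one chance acceptance) in >= 90% of
        seeds.  Strict-improvement acceptance on CV estimates admits an
        occasional noise feature by chance; that is inherent to the greedy
        rule, hence the one-feature allowance."""
        clean = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 50)
            strong = 3.0 * y + rng.standard_normal(100)
            useful = 0.8 * y + rng.standard_normal(100)
            X = np.column_stack([strong, useful, rng.standard_normal((100, 4))])
            t = make_numeric_table(X, y)
            cfg = HcmfsConfig(model=LR_CFG, seed=seed)
            res = forward_search(t, ["f0"], cfg)
            accepted_noise = [f for f in res.subset if f not in ("f0", "f1")]
            clean += len(accepted_noise) <= 1
        assert clean >= 27

    def test_empty_feature_table_is_error(self):
        import pandas as pd

        from hcmfs import FeatureTable

        t = FeatureTable.from_dataframe(pd.DataFrame(index=range(4)), [0, 0, 1, 1])
        with pytest.raises(ValueError, match="empty"):
            forward_search(t, [], HcmfsConfig(model=KNN1, cv_folds=2))


class TestBackwardSearch:
    def test_seed_features_never_removed(self, planted_table):
        cfg = HcmfsConfig(model=LR_CFG, seed=2)
        seed = ["signal_01", "noise_03"]
        res = backward_search(planted_table, seed, cfg)
        assert set(seed) <= set(res.subset)

    def test_duplicated_feature_removed(self, redundant_table):
        cfg = HcmfsConfig(model=KNN1, seed=0)
        res = backward_search(redundant_table, ["f0"], cfg)
        assert "f1" not in res.subset  # removing an exact duplicate never hurts

    def test_noise_features_mostly_pruned(self):
        """Starting from the full set, most non-seed noise features are
        dropped in at least 90% of seeds."""
        pruned = 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            y = np.repeat([0, 1], 30)
            strong = 1.5 * y + rng.standard_normal(60)
            X = np.column_stack([strong, rng.standard_normal((60, 4))])
            t = make_numeric_table(X, y)
            cfg = HcmfsConfig(model=LR_CFG, seed=seed)
            res = backward_search(t, ["f0"], cfg)
            pruned += len(res.subset) < 5
        assert pruned >= 27


class TestChooseRule:
    def r(self, direction, acc, size):
        return SelectionResult([f"f{i}" for i in range(size)], direction, [(size, acc)], acc)

    def test_higher_accuracy_wins(self):
        assert _choose(self.r("forward", 0.9, 5), self.r("backward", 0.8, 3)).direction == "forward"
        assert _choose(self.r("forward", 0.7, 5), self.r("backward", 0.8, 9)).direction == "backward"

    def test_tie_prefers_smaller_subset(self):
        assert _choose(self.r("forward", 0.8, 5), self.r("backward", 0.8, 3)).direction == "backward"
        assert _choose(self.r("forward", 0.8, 2), self.r("backward", 0.8, 3)).direction == "forward"

    def test_full_tie_prefers_forward(self):
        assert _choose(self.r("forward", 0.8, 3), self.r("backward", 0.8, 3)).direction == "forward"


class TestHcMfsSelect:
    def test_deterministic_given_seed(self, planted_table):
        cfg = HcmfsConfig(model=LR_CFG, seed=5)
        a = hc_mfs_select(planted_table, cfg)
        b = hc_mfs_select(planted_table, cfg)
        assert a.subset == b.subset
        assert a.direction == b.direction
        assert a.final_accuracy == b.final_accuracy

    def test_final_accuracy_at_least_seed_subset_accuracy(self, planted_table):
        cfg = HcmfsConfig(model=LR_CFG, seed=5)
        res = hc_mfs_select(planted_table, cfg)
        folds = fold_indices(planted_table.labels.to_numpy(), cfg.cv_folds, cfg.seed)
        seed_acc = mean_cv_accuracy(
            planted_table, res.meta["initial_subset"], cfg.model.build(), folds
        )
        assert res.final_accuracy >= seed_acc - 1e-12

    def test_reports_both_directions(self, planted_table):
        res = hc_mfs_select(planted_table, HcmfsConfig(model=LR_CFG, seed=5))
        assert res.direction in ("forward", "backward")
        assert 0.0 <= res.meta["forward_accuracy"] <= 1.0
        assert 0.0 <= res.meta["backward_accuracy"] <= 1.0
        assert len(res.meta["class_means"]) == 3

    def test_backward_winner_is_reachable(self):
        """Across seeds the pipeline produces backward winners too."""
        directions = set()
        for seed in range(8):
            from hcmfs import generate_cohort, planted_spec

            t = generate_cohort(planted_spec(n_per_group=80), 500 + seed)
            directions.add(hc_mfs_select(t, HcmfsConfig(model=LR_CFG, seed=seed)).direction)
            if len(directions) == 2:
                break
        assert directions == {"forward", "backward"}

    def test_subset_stable_under_column_permutation(self, planted_table):
        cfg = HcmfsConfig(model=LR_CFG, seed=3)
        base = hc_mfs_select(planted_table, cfg)
        cols = planted_table.feature_names[::-1]
        permuted = planted_table.copy()
        permuted.values = permuted.values[cols]
        permuted.meta = {c: permuted.meta[c] for c in cols}
        perm = hc_mfs_select(permuted, cfg)
        assert set(base.subset) == set(perm.subset)
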