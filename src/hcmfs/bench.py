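"""Classifier configurations, cross-validated evaluation and metrics.

Five classical classifiers (KNN, random forest, linear SVM, Gaussian naive
Bayes, logistic regression) are delegated to scikit-learn; this module's
contribution is the harness: frozen stratified fold partitions so that
competing feature-selection methods are compared on identical splits,
per-fold standardization (training-fold statistics only), exhaustive grid
search by mean CV accuracy, and the metric bundle used in the benchmark
tables (accuracy, precision, recall, F1, AUC, RMSE, R, residual SD).

For hard 0/1 predictions RMSE^2 = 1 - accuracy holds exactly: a prediction
vector with 124 of 136 correct gives accuracy 0.9118 and RMSE 0.2970.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import FeatureTable

MODEL_NAMES = ("KNN", "RF", "SVM", "NB", "LR")
SELECTION_METHODS = ("HCMFS", "FS", "R_F", "MI", "DCFS")


@dataclass(frozen=True)
class ModelConfig:
    """One classifier configuration tied to a dataset variant."""

    model: str
    params: dict = field(default_factory=dict)
    dataset_variant: str = "IMV+SS"

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODEL_NAMES}")

    def build(self):
        return make_estimator(self.model, self.params)

    @property
    def scale_in_fold(self) -> bool:
        return "SS" in self.dataset_variant


def make_estimator(model: str, params: dict | None = None):
    """Instantiate a scikit-learn classifier for one of the five models."""
    p = dict(params or {})
    if model == "KNN":
        return KNeighborsClassifier(
            n_neighbors=int(p.get("n_neighbors", 5)),
            p=int(p.get("p", 2)),
            weights=p.get("weights", "uniform"),
        )
    if model == "RF":
        return RandomForestClassifier(
            max_depth=p.get("max_depth"),
            n_estimators=int(p.get("n_estimators", 100)),
            random_state=int(p.get("random_state", 0)),
        )
    if model == "SVM":
        return SVC(C=float(p.get("C", 1.0)), kernel=p.get("kernel", "linear"))
    if model == "NB":
        return GaussianNB()
    if model == "LR":
        # penalty expressed through l1_ratio (the penalty= parameter is
        # deprecated in recent scikit-learn)
        l1_ratio = {"l1": 1.0, "l2": 0.0}[str(p.get("penalty", "l2")).lower()]
        return LogisticRegression(
            solver=p.get("solver", "liblinear"),
            l1_ratio=l1_ratio,
            C=float(p.get("C", 1.0)),
            max_iter=int(p.get("max_iter", 1000)),
        )
    raise ValueError(f"unknown model {model!r}")


def published_model_settings() -> dict:
    """Per-(selection-method, model) classifier settings shipped with the
    package, as used in the original benchmark."""
    with resources.files("hcmfs.data").joinpath("model_settings.json").open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# folds and accuracy


def fold_indices(y, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Frozen stratified fold partition; reused across every comparison so
    accuracy differences are paired."""
    y = np.asarray(y)
    if folds > np.bincount(y.astype(int)).min():
        raise ValueError("fold count exceeds smallest class count")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def fold_hash(folds_idx) -> str:
    h = hashlib.sha256()
    for tr, te in folds_idx:
        h.update(np.asarray(te, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


def _fit_predict(estimator, Xtr, ytr, Xte, scale: bool):
    est = clone(estimator)
    if scale:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    est.fit(Xtr, ytr)
    yhat = est.predict(Xte)
    if hasattr(est, "predict_proba"):
        score = est.predict_proba(Xte)[:, 1]
    elif hasattr(est, "decision_function"):
        score = est.decision_function(Xte)
    else:
        score = yhat.astype(float)
    return yhat, score


def mean_cv_accuracy(
    table: FeatureTable, subset, estimator, folds_idx, scale: bool = False
) -> float:
    """Mean over folds of held-out accuracy for one feature subset.

    An empty subset is scored by the training-fold majority class, the
    natural baseline for a featureless model.
    """
    y = table.labels.to_numpy()
    accs = []
    for tr, te in folds_idx:
        if np.unique(y[tr]).size < 2:
            raise ValueError("degenerate single-class training fold")
        if not subset:
            maj = np.bincount(y[tr].astype(int)).argmax()
            accs.append(float((y[te] == maj).mean()))
            continue
        X = table.values[list(subset)].to_numpy(dtype=float)
        yhat, _ = _fit_predict(estimator, X[tr], y[tr], X[te], scale)
        accs.append(float((yhat == y[te]).mean()))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class EvalReport:
    """Metric bundle for one method/model pair."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    rmse: float
    r: float
    std: float
    confusion: tuple[tuple[int, int], tuple[int, int]]
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "rmse": self.rmse,
            "r": self.r,
            "std": self.std,
        }
        return d


def compute_metrics(y, yhat, scores=None) -> EvalReport:
    """Classification metrics for class 1 plus the error bundle.

    RMSE is computed on the 0/1 labels; R is the Pearson correlation of true
    and predicted labels (0 when either is constant); std is the sample
    standard deviation of the signed residuals y - yhat.  AUC (rank
    statistic) is reported only when continuous scores are supplied.
    """
    y = np.asarray(y, dtype=int)
    yhat = np.asarray(yhat, dtype=int)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat length mismatch")
    tp = int(((y == 1) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    total = y.size
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    resid = y.astype(float) - yhat.astype(float)
    rmse = float(np.sqrt(np.mean(resid**2)))
    if y.std() == 0 or yhat.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
    std = float(resid.std(ddof=1)) if total > 1 else 0.0
    auc = None
    if scores is not None and np.unique(y).size == 2:
        auc = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    return EvalReport(
        accuracy=float(accuracy),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        auc=auc,
        rmse=rmse,
        r=r,
        std=std,
        confusion=((tn, fp), (fn, tp)),
    )


def cross_validate(
    table: FeatureTable,
    subset,
    config: ModelConfig,
    folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold evaluation of one feature subset.

    Standardization (for ``*+SS`` variants) uses training-fold statistics
    only; metrics are pooled over the held-out predictions of all folds.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    table.require_complete("cross_validate")
    y = table.labels.to_numpy()
    folds_idx = fold_indices(y, folds, seed)
    X = table.values[subset].to_numpy(dtype=float)
    est = config.build()
    yhat = np.empty_like(y)
    score = np.empty(y.size, dtype=float)
    for tr, te in folds_idx:
        if np.unique(y[tr]).size < 2:
            raise ValueError("degenerate single-class training fold")
        yhat[te], score[te] = _fit_predict(est, X[tr], y[tr], X[te], config.scale_in_fold)
    rep = compute_metrics(y, yhat, scores=score)
    rep.meta.update(
        {"fold_hash": fold_hash(folds_idx), "model": config.model, "subset": subset}
    )
    return rep


def grid_search(
    table: FeatureTable,
    subset,
    model: str,
    grid: dict[str, list],
    folds: int = 5,
    seed: int = 0,
    dataset_variant: str = "IMV+SS",
) -> ModelConfig:
    """Exhaustive grid search by mean CV accuracy.

    The grid is enumerated in the given key/value order; ties keep the first
    configuration encountered.  Deterministic given seed.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    y = table.labels.to_numpy()
    folds_idx = fold_indices(y, folds, seed)
    keys = list(grid)
    best: tuple[float, ModelConfig] | None = None
    for values in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, values))
        cfg = ModelConfig(model, params, dataset_variant)
        acc = mean_cv_accuracy(table, list(subset), cfg.build(), folds_idx, cfg.scale_in_fold)
        if best is None or acc > best[0]:
            best = (acc, cfg)
    return best[1]


def compare_methods(
    table: FeatureTable,
    model_config: ModelConfig,
    methods=SELECTION_METHODS,
    k: int = 12,
    folds: int = 5,
    seed: int = 0,
    hcmfs_config=None,
) -> dict[str, EvalReport]:
    """Benchmark HC-MFS against the filter baselines at a fixed subset size.

    Each filter contributes its top-k ranking; HC-MFS contributes the subset
    its own search selects.  Every method is evaluated with the same model
    and the identical frozen fold partition.
    """
    from . import selection
    from .scores import rank_features

    if k > len(table.feature_names):
        raise ValueError("k exceeds number of features")
    reports: dict[str, EvalReport] = {}
    for method in methods:
        if method == "HCMFS":
            cfg = hcmfs_config or selection.HcmfsConfig(seed=seed, cv_folds=folds)
            subset = selection.hc_mfs_select(table, cfg).subset
        elif method in ("FS", "MI", "DCFS"):
            subset = rank_features(table, method).top_k(k)
        elif method == "R_F":
            subset = rank_features(table, "R_F", seed=seed).top_k(k)
        else:
            raise ValueError(f"unknown selection method {method!r}")
        reports[method] = cross_validate(table, subset, model_config, folds, seed)
    return reports
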