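"""Supervised protocol for severely imbalanced rare-case detection.

For each of R repeated stratified train/test splits: random-forest
importance-based feature selection, cluster-centroid undersampling of the
majority (control) class down to the minority size, grid-searched
classification with 5-fold cross-validation inside the training set, and
scoring of the untouched test set.  Feature selection and undersampling are
refit inside every CV fold so no validation patient leaks into
preprocessing; the test set is never undersampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import RidgeClassifier
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import evaluation
from .representation import Cohort

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31

CLASSIFIER_FAMILIES = ("ridge", "svm", "rf", "xgboost")

#: Hyperparameter grids searched inside the training-set cross-validation.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "ridge": [{"alpha": a} for a in (0.01, 0.1, 1.0, 10.0)],
    "svm": [
        {"C": c, "gamma_scale": g}
        for c, g in product((0.1, 1.0, 10.0), (0.5, 1.0, 2.0))
    ],
    "rf": [
        {"n_estimators": 200, "max_depth": d, "min_samples_leaf": l}
        for d, l in product((None, 10), (1, 5))
    ],
    "xgboost": [
        {"n_estimators": 200, "max_depth": d, "learning_rate": lr}
        for d, lr in product((3, 6), (0.05, 0.1))
    ],
}


@dataclass(frozen=True)
class PipelineConfig:
    similarity_method: str = "restricted_lin"
    classifier: str = "rf"
    grids: Mapping[str, list[dict]] = field(default_factory=lambda: DEFAULT_GRIDS)
    cv_folds: int = 5
    repeats: int = 10
    test_fraction: float = 0.33
    fs_n_estimators: int = 200           # trees in the feature-selection forest
    undersample_k: int | None = None     # None -> minority-class size
    kmeans_restarts: int = 10
    kmeans_max_iter: int = 300
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIER_FAMILIES:
            raise ValueError(f"classifier must be one of {CLASSIFIER_FAMILIES}")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if not self.grids.get(self.classifier):
            raise ValueError(f"empty hyperparameter grid for {self.classifier!r}")


@dataclass(frozen=True)
class SplitPlan:
    repeat_index: int
    seed: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass
class FittedPipeline:
    family: str
    selected: np.ndarray            # indices into the feature space, ascending
    estimator: object
    best_params: dict
    metadata: dict = field(default_factory=dict)


def make_splits(cohort: Cohort, config: PipelineConfig) -> list[SplitPlan]:
    """R stratified holdout splits with seeds derived from the master seed."""
    y = cohort.labels
    ids = np.array(cohort.patient_ids)
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError("each class needs at least 2 members for stratified splits")
    plans = []
    for r in range(config.repeats):
        seed = (config.master_seed + r) % _SEED_MOD
        sss = StratifiedShuffleSplit(
            n_splits=1, test_size=config.test_fraction, random_state=seed
        )
        train_idx, test_idx = next(sss.split(np.zeros((len(y), 1)), y))
        plans.append(
            SplitPlan(
                repeat_index=r,
                seed=seed,
                train_ids=tuple(ids[train_idx]),
                test_ids=tuple(ids[test_idx]),
            )
        )
    return plans


def select_features(
    x: np.ndarray,
    y: np.ndarray,
    *,
    n_estimators: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Indices of features with RF impurity importance >= the mean importance.

    Input order (ascending index) is preserved.  If the forest assigns every
    feature an importance below the mean (only possible in degenerate cases,
    e.g. all-constant features), the single most important feature is kept.
    """
    if x.shape[1] < 2:
        raise ValueError("feature selection needs at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs both classes")
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed % _SEED_MOD, n_jobs=1
    )
    forest.fit(x, y)
    importances = forest.feature_importances_
    keep = np.flatnonzero(importances >= importances.mean())
    if keep.size == 0 or not np.any(importances > 0):
        logger.warning("feature selection degenerate; falling back to top-1 feature")
        keep = np.array([int(np.argmax(importances))])
    return keep


def undersample_cluster_centroids(
    majority_vectors: np.ndarray,
    k: int,
    *,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> np.ndarray:
    """Replace the majority class by the k-means centroids of its points.

    Centroid coordinates may be fractional even when the inputs are binary:
    a centroid is the mean of its cluster, a prototype control rather than an
    observed one.  Restart ties are resolved by sklearn (lowest inertia).
    """
    n = majority_vectors.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available majority samples")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=seed % _SEED_MOD,
    )
    km.fit(majority_vectors)
    return km.cluster_centers_


def _balance(
    x: np.ndarray, y: np.ndarray, config: PipelineConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Undersample the majority class to the minority size (or configured k)."""
    minority = 1 if (y == 1).sum() <= (y == 0).sum() else 0
    x_min, x_maj = x[y == minority], x[y != minority]
    k = config.undersample_k if config.undersample_k is not None else len(x_min)
    centroids = undersample_cluster_centroids(
        x_maj, k, seed=seed,
        n_restarts=config.kmeans_restarts, max_iter=config.kmeans_max_iter,
    )
    xb = np.vstack([x_min, centroids])
    yb = np.concatenate([np.full(len(x_min), minority), np.full(k, 1 - minority)])
    return xb, yb


def _make_estimator(family: str, params: dict, seed: int, x: np.ndarray):
    seed = seed % _SEED_MOD
    if family == "ridge":
        return RidgeClassifier(alpha=params["alpha"])
    if family == "svm":
        var = x.var()
        gamma = params["gamma_scale"] / (x.shape[1] * var) if var > 0 else 1.0
        return SVC(kernel="rbf", C=params["C"], gamma=gamma, random_state=seed)
    if family == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "xgboost":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss",
            tree_method="hist", verbosity=0, **params,
        )
    raise ValueError(f"unknown classifier family {family!r}")


def _scores_of(estimator, x: np.ndarray) -> np.ndarray:
    """Case scores in [0, 1]: native probability, or a sigmoid of the margin."""
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(x)[:, 1]
    return expit(estimator.decision_function(x))


def grid_search_fit(
    x: np.ndarray, y: np.ndarray, config: PipelineConfig, seed: int = 0
) -> FittedPipeline:
    """Select hyperparameters by 5-fold CV mean average precision; refit.

    Feature selection and undersampling are refit on each CV fold's training
    part, never on its validation part; the final model is refit with the
    whole training set.  Model selection uses average precision, the metric
    suited to the extreme class imbalance.
    """
    grid = config.grids[config.classifier]
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed % _SEED_MOD)
    folds = []
    fold_feature_counts = []
    for fold_i, (tr, va) in enumerate(skf.split(x, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            raise ValueError(f"CV fold {fold_i} contains a single class")
        sel = select_features(
            x[tr], y[tr], n_estimators=config.fs_n_estimators, seed=seed + fold_i
        )
        fold_feature_counts.append(int(sel.size))
        xb, yb = _balance(x[tr][:, sel], y[tr], config, seed + fold_i)
        folds.append((xb, yb, x[va][:, sel], y[va]))

    mean_ap = []
    for params in grid:
        aps = []
        for xb, yb, xva, yva in folds:
            est = _make_estimator(config.classifier, params, seed, xb)
            est.fit(xb, yb)
            aps.append(average_precision_score(yva, _scores_of(est, xva)))
        mean_ap.append(float(np.mean(aps)))
    best_i = int(np.argmax(mean_ap))  # ties -> first combination in grid order

    sel = select_features(x, y, n_estimators=config.fs_n_estimators, seed=seed)
    xb, yb = _balance(x[:, sel], y, config, seed)
    est = _make_estimator(config.classifier, grid[best_i], seed, xb)
    est.fit(xb, yb)
    return FittedPipeline(
        family=config.classifier,
        selected=sel,
        estimator=est,
        best_params=dict(grid[best_i]),
        metadata={
            "cv_fold_feature_counts": fold_feature_counts,
            "cv_mean_average_precision": mean_ap,
            "final_feature_count": int(sel.size),
        },
    )


def score(
    fitted: FittedPipeline, x: np.ndarray, patient_ids: Sequence[str]
) -> dict[str, float]:
    """Case-likeness score in [0, 1] per patient; higher = more case-like."""
    if len(patient_ids) != x.shape[0]:
        raise ValueError("patient_ids length does not match the vector matrix")
    if x.shape[1] <= int(fitted.selected.max()):
        raise ValueError("vector matrix does not cover the fitted feature space")
    s = _scores_of(fitted.estimator, x[:, fitted.selected])
    return {pid: float(v) for pid, v in zip(patient_ids, s)}


def run_protocol(
    cohort: Cohort,
    x: np.ndarray,
    config: PipelineConfig,
    *,
    specificity: float = 0.90,
    k_percents: Sequence[float] = (1.0, 10.0),
) -> tuple["evaluation.EvaluationReport", dict[str, float]]:
    """Full repeated-split protocol on a vectorized cohort.

    ``x`` rows align with ``cohort`` order.  Returns the evaluation report
    and, for ranking output, each patient's mean test-set score across the
    repetitions in which they fell into a test set.
    """
    ids = cohort.patient_ids
    row = {pid: i for i, pid in enumerate(ids)}
    labels = {pid: int(lab) for pid, lab in zip(ids, cohort.labels)}
    plans = make_splits(cohort, config)
    per_rep = []
    score_sums: dict[str, float] = {}
    score_counts: dict[str, int] = {}
    for plan in plans:
        tr = np.array([row[pid] for pid in plan.train_ids])
        te = np.array([row[pid] for pid in plan.test_ids])
        fitted = grid_search_fit(x[tr], cohort.labels[tr], config, seed=plan.seed)
        test_scores = score(fitted, x[te], list(plan.test_ids))
        metrics = evaluation.evaluate_scores(
            test_scores, labels, specificity=specificity, k_percents=k_percents
        )
        metrics["repeat_index"] = plan.repeat_index
        metrics["best_params"] = fitted.best_params
        metrics["n_selected_features"] = fitted.metadata["final_feature_count"]
        per_rep.append(metrics)
        for pid, s in test_scores.items():
            score_sums[pid] = score_sums.get(pid, 0.0) + s
            score_counts[pid] = score_counts.get(pid, 0) + 1
    numeric = [
        {k: v for k, v in rep.items()
         if k != "repeat_index" and isinstance(v, (int, float))}
        for rep in per_rep
    ]
    report = evaluation.EvaluationReport(
        per_repetition=tuple(per_rep),
        aggregate=evaluation.aggregate(numeric) if len(numeric) >= 2 else
        {k: {"mean": v} for k, v in numeric[0].items()},
        config={
            "classifier": config.classifier,
            "similarity_method": config.similarity_method,
            "repeats": config.repeats,
            "cv_folds": config.cv_folds,
            "test_fraction": config.test_fraction,
            "master_seed": config.master_seed,
            "specificity_target": specificity,
            "k_percents": list(k_percents),
        },
    )
    mean_scores = {pid: score_sums[pid] / score_counts[pid] for pid in score_sums}
    return report, mean_scores
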