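"""Classifier families, grid search, leave-one-out validation, F-beta metrics.

Four families are supported: L2-penalized logistic regression, random forest,
support-vector machine (RBF, Platt-calibrated probabilities) and gradient
boosted trees. Because a missed MAS diagnosis is far costlier than a false
alarm, evaluation reports the recall-weighted F2 score alongside F1 and the
rank-based ROC-AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .synth import CohortTable

__all__ = [
    "ModelSpec",
    "EvalMetrics",
    "FAMILIES",
    "default_model_specs",
    "f_beta",
    "roc_auc",
    "grid_search_fit",
    "loo_validate",
    "evaluate_suite",
]

FAMILIES = ("l2_logistic", "random_forest", "svm", "gradient_boosting")


@dataclass(frozen=True)
class ModelSpec:
    family: str
    grid: Mapping[str, tuple] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        for k, v in self.grid.items():
            if len(v) == 0:
                raise ValueError(f"empty candidate list for grid parameter {k!r}")


def default_model_specs(seed: int = 0) -> dict[str, ModelSpec]:
    """Compact default grids for the four families."""
    return {
        "l2_logistic": ModelSpec("l2_logistic", {"C": (0.01, 0.1, 1.0, 10.0)}, seed),
        "random_forest": ModelSpec(
            "random_forest", {"n_estimators": (200,), "max_depth": (3, 6, None)}, seed),
        "svm": ModelSpec("svm", {"C": (0.1, 1.0, 10.0), "gamma": ("scale",)}, seed),
        "gradient_boosting": ModelSpec(
            "gradient_boosting",
            {"n_estimators": (150,), "max_depth": (2, 3), "learning_rate": (0.1,)}, seed),
    }


def _base_estimator(family: str, seed: int):
    if family == "l2_logistic":
        # L2 penalty is always active for this family
        return LogisticRegression(solver="lbfgs", max_iter=5000)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if family == "svm":
        # probability=True fits a sigmoid on internal held-out folds (Platt)
        return SVC(kernel="rbf", probability=True, random_state=seed)
    return XGBClassifier(random_state=seed, eval_metric="logloss",
                         n_jobs=1, verbosity=0)


def f_beta(precision: float, recall: float, beta: float) -> float:
    """Weighted harmonic mean (1+β²)·P·R / (β²·P + R); β=2 weights recall
    four times as heavily as precision. Defined as 0 when P = R = 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if beta <= 0:
        raise ValueError("beta must be positive")
    if precision == 0.0 and recall == 0.0:
        warnings.warn("precision and recall both zero; F-score defined as 0")
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * precision * recall / (b2 * precision + recall)


def roc_auc(scores, labels) -> float:
    """Rank-based AUC: the probability that a random positive outscores a
    random negative, ties counted half (Mann-Whitney U normalization)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)  # average ranks handle ties
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


@dataclass
class EvalMetrics:
    auc: float
    f1: float
    f2: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5

    @classmethod
    def from_scores(cls, scores, labels, threshold: float = 0.5) -> "EvalMetrics":
        s = np.asarray(scores, float)
        y = np.asarray(labels, int)
        pred = (s >= threshold).astype(int)
        tp = int(np.sum((pred == 1) & (y == 1)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        tn = int(np.sum((pred == 0) & (y == 0)))
        fn = int(np.sum((pred == 0) & (y == 1)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = f_beta(precision, recall, 1.0)
            f2 = f_beta(precision, recall, 2.0)
        return cls(roc_auc(s, y), f1, f2, tp, fp, tn, fn, threshold)


def grid_search_fit(train: CohortTable, spec: ModelSpec, inner_folds: int = 5):
    """Exhaustive grid evaluation by stratified inner CV on the training
    split; the best configuration is refit on all training data. Returns
    (fitted estimator, chosen hyperparameters)."""
    y = train.label
    if len(np.unique(y)) < 2:
        raise ValueError("training split must contain both classes")
    base = _base_estimator(spec.family, spec.seed)
    grid = {k: list(v) for k, v in spec.grid.items()}
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(base, grid, scoring="roc_auc", cv=cv, refit=True)
    search.fit(train.frame.to_numpy(float), y)
    return search.best_estimator_, dict(search.best_params_)


def loo_validate(train: CohortTable, spec: ModelSpec,
                 params: Mapping | None = None, threshold: float = 0.5) -> EvalMetrics:
    """Leave-one-out validation: n fits, each scoring its held-out patient;
    metrics are computed on the pooled out-of-fold predictions."""
    X = train.frame.to_numpy(float)
    y = train.label
    if len(y) < 10:
        raise ValueError("leave-one-out validation needs n >= 10")
    scores = np.full(len(y), np.nan)
    failed: list[int] = []
    for i, (tr, te) in enumerate(LeaveOneOut().split(X)):
        model = _base_estimator(spec.family, spec.seed)
        if params:
            model.set_params(**params)
        try:
            model.fit(X[tr], y[tr])
            scores[te] = model.predict_proba(X[te])[:, 1]
        except Exception as exc:  # convergence failure on a fold
            failed.append(i)
            warnings.warn(f"leave-one-out fold {i} failed: {exc}")
    ok = ~np.isnan(scores)
    return EvalMetrics.from_scores(scores[ok], y[ok], threshold)


def evaluate_suite(models: Mapping[str, object],
                   splits: Mapping[str, CohortTable],
                   threshold: float = 0.5) -> pd.DataFrame:
    """Score every fitted model on every split; one row per (model, split)
    with AUC, F1, F2 and the confusion counts at ``threshold``."""
    schemas = {tuple(c.frame.columns) for c in splits.values()}
    if len(schemas) > 1:
        raise ValueError("splits do not share a feature schema")
    rows = []
    for mname, model in models.items():
        for sname, cohort in splits.items():
            scores = model.predict_proba(cohort.frame.to_numpy(float))[:, 1]
            m = EvalMetrics.from_scores(scores, cohort.label, threshold)
            rows.append({"model": mname, "split": sname, "auc": m.auc,
                         "f1": m.f1, "f2": m.f2, "tp": m.tp, "fp": m.fp,
                         "tn": m.tn, "fn": m.fn})
    return pd.DataFrame(rows)
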