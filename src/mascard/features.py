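"""Two-stage feature selection.

Stage one removes redundancy: of any feature pair with |Pearson r| at or above
a cutoff, the member less correlated (point-biserial) with the diagnosis is
dropped; remaining multicollinearity is pruned by iteratively removing the
feature with the largest variance inflation factor. Clinically motivated
composites (pancytopenia, liver damage) can replace their five source
analytes. Stage two is an L1-penalized logistic regression (LASSO) over a
log-spaced penalty grid, the penalty chosen by k-fold cross-validated binomial
deviance under the one-standard-error rule, and the selected set read off the
nonzero coefficients of the refit at that penalty.

Ties everywhere break by ascending feature name so selection is invariant to
column order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .synth import CohortTable

__all__ = [
    "SelectionReport",
    "pearson_filter",
    "vif_filter",
    "make_composites",
    "lasso_select",
]


def pearson_filter(cohort: CohortTable, r_threshold: float = 0.8
                   ) -> tuple[CohortTable, list[tuple[str, str, float]]]:
    """Drop one member of every feature pair with |r| >= ``r_threshold``.

    The member with the weaker absolute point-biserial correlation to the
    label is removed (ties by ascending name, the alphabetically first kept).
    Constant features have no defined correlation and are dropped with a
    warning. Returns the reduced cohort and [(removed, kept, |r|), ...].
    """
    frame = cohort.frame.copy()
    removed: list[tuple[str, str, float]] = []
    const = [c for c in frame.columns if frame[c].nunique() <= 1]
    for c in const:
        warnings.warn(f"constant feature {c!r} dropped (correlation undefined)")
        removed.append((c, "", float("nan")))
    frame = frame.drop(columns=const)

    y = cohort.label.astype(float)
    label_r = {c: abs(float(np.corrcoef(frame[c], y)[0, 1])) for c in frame.columns}
    while True:
        cols = sorted(frame.columns)
        if len(cols) < 2:
            break
        corr = frame[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < r_threshold:
            break
        a, b = cols[min(i, j)], cols[max(i, j)]
        # drop the member less informative about the label; tie keeps `a`
        drop, keep = (b, a) if label_r[b] <= label_r[a] else (a, b)
        removed.append((drop, keep, float(corr[i, j])))
        frame = frame.drop(columns=[drop])
    return CohortTable(frame, cohort.label.copy(),
                       None if cohort.outcome is None else cohort.outcome.copy()), removed


def vif_filter(cohort: CohortTable, vif_threshold: float = 10.0
               ) -> tuple[CohortTable, list[tuple[str, float]]]:
    """Iteratively remove the feature with the largest VIF until all are below
    ``vif_threshold``. Exact linear dependence (infinite VIF) is resolved by
    removing one member deterministically (largest VIF, ties by name)."""
    frame = cohort.frame.copy()
    removed: list[tuple[str, float]] = []
    while frame.shape[1] >= 2:
        cols = sorted(frame.columns)
        X = np.column_stack([frame[cols].to_numpy(float),
                             np.ones(len(frame))])  # intercept for the auxiliary fits
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # statsmodels divides by zero on exact collinearity
            vifs = np.array([variance_inflation_factor(X, k) for k in range(len(cols))])
        vifs = np.where(np.isnan(vifs), np.inf, vifs)
        worst = int(np.argmax(vifs))  # argmax takes the first (lowest name) on ties
        if vifs[worst] < vif_threshold:
            break
        removed.append((cols[worst], float(vifs[worst])))
        frame = frame.drop(columns=[cols[worst]])
    return CohortTable(frame, cohort.label.copy(),
                       None if cohort.outcome is None else cohort.outcome.copy()), removed


_PANCYTOPENIA_SOURCES = ("HB", "PLT", "WBC")
_LIVER_SOURCES = ("ALT", "AST")


def make_composites(cohort: CohortTable, ranges: dict[str, tuple[float, float]]
                    ) -> CohortTable:
    """Replace HB/PLT/WBC/ALT/AST with two clinical composites.

    Pancytopenia requires depression of all three lineages (HB, PLT and WBC
    each strictly below its lower reference limit); liver damage is an
    elevation of either transaminase (ALT or AST strictly above its upper
    limit). The five source columns are dropped.
    """
    sources = (*_PANCYTOPENIA_SOURCES, *_LIVER_SOURCES)
    for name in sources:
        if name not in cohort.frame.columns:
            raise ValueError(f"composite source column {name!r} is missing")
        if name not in ranges:
            raise ValueError(f"normal range for {name!r} is missing")
    frame = cohort.frame.copy()
    pancy = np.ones(len(frame), dtype=float)
    for name in _PANCYTOPENIA_SOURCES:
        pancy *= (frame[name] < ranges[name][0]).to_numpy(float)
    liver = np.zeros(len(frame), dtype=float)
    for name in _LIVER_SOURCES:
        liver = np.maximum(liver, (frame[name] > ranges[name][1]).to_numpy(float))
    frame = frame.drop(columns=list(sources))
    frame["pancytopenia"] = pancy
    frame["liver_damage"] = liver
    return CohortTable(frame, cohort.label.copy(),
                       None if cohort.outcome is None else cohort.outcome.copy())


@dataclass
class SelectionReport:
    lambda_grid: list[float]
    cv_deviance: list[float]      # mean held-out binomial deviance per lambda
    best_lambda: float
    selected: list[str]           # nonzero-coefficient features, ascending name
    coefficients: dict[str, float] = field(default_factory=dict)
    n_active: list[int] = field(default_factory=list)  # nonzero count per lambda (full-data refit)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    # probabilities clamped at 1e-5 (glmnet's convention) so a single
    # confidently misclassified held-out point cannot dominate a fold
    eps = 1e-5
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_select(cohort: CohortTable, lambda_grid: np.ndarray | None = None,
                 k_folds: int = 5, seed: int = 0, n_lambda: int = 40,
                 rule: str = "1se") -> SelectionReport:
    """L1-logistic feature selection with stratified k-fold cross-validation.

    The grid defaults to ``n_lambda`` log-spaced penalties from the smallest
    value that zeroes every coefficient (the null-model penalty
    max|Xᵀ(y − ȳ)|/n) down 3.5 decades. The per-observation penalty λ maps to
    scikit-learn's C as 1/(n·λ). Cross-validated binomial deviance scores
    each λ; ``rule="1se"`` (default) picks the largest λ within one standard
    error of the minimum, the standard guard against the noise overselection
    of the plain minimum, which remains available as ``rule="min"``. The
    selected set is read from a full-data refit at the chosen λ.
    """
    if rule not in ("1se", "min"):
        raise ValueError(f"unknown selection rule {rule!r}")
    y = cohort.label.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("label is degenerate: only one class present")
    cols = sorted(cohort.frame.columns)
    X = cohort.frame[cols].to_numpy(float)
    n = len(y)
    if lambda_grid is None:
        lam_max = float(np.max(np.abs(X.T @ (y - y.mean()))) / n)
        lambda_grid = np.logspace(np.log10(lam_max), np.log10(lam_max) - 3.5, n_lambda)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), float)

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    fold_dev = np.zeros((len(folds), len(lambda_grid)))
    for f, (tr, te) in enumerate(folds):
        for i, lam in enumerate(lambda_grid):
            model = LogisticRegression(solver="liblinear", l1_ratio=1, random_state=0,
                                       C=1.0 / (len(tr) * lam), max_iter=2000)
            model.fit(X[tr], y[tr])
            fold_dev[f, i] = _deviance(y[te], model.predict_proba(X[te])[:, 1])
    cv_dev = fold_dev.mean(axis=0)

    min_i = int(np.argmin(cv_dev))
    if rule == "min":
        best_i = min_i
    else:
        se = float(fold_dev[:, min_i].std(ddof=1) / np.sqrt(len(folds)))
        within = np.where(cv_dev <= cv_dev[min_i] + se)[0]
        best_i = int(within[0])  # grid descends in lambda: first hit = largest
    best_lambda = float(lambda_grid[best_i])
    n_active: list[int] = []
    best_coef = None
    for lam in lambda_grid:
        model = LogisticRegression(solver="liblinear", l1_ratio=1, random_state=0,
                                   C=1.0 / (n * lam), max_iter=2000)
        model.fit(X, y)
        coef = model.coef_.ravel()
        n_active.append(int(np.sum(coef != 0)))
        if lam == best_lambda:
            best_coef = coef
    selected = [c for c, b in zip(cols, best_coef) if b != 0]
    return SelectionReport(
        lambda_grid=[float(v) for v in lambda_grid],
        cv_deviance=[float(v) for v in cv_dev],
        best_lambda=best_lambda,
        selected=selected,
        coefficients={c: float(b) for c, b in zip(cols, best_coef) if b != 0},
        n_active=n_active,
    )
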