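"""Diagnostic scorecard construction for MAS secondary to SLE.

The scorecard follows standard credit-scoring practice adapted to diagnosis:

1. Each continuous predictor is discretized by bottom-up chi-square (ChiMerge)
   binning; each binary predictor keeps its two categories as bins.
2. Every bin receives a weight of evidence WOE = ln(SLE% / MAS%), the log
   ratio of the class-conditional bin shares, so high WOE marks SLE-typical
   values and low (negative) WOE marks MAS-typical values.
3. A logistic regression on the WOE-encoded features yields an intercept and
   per-feature weights; the linear predictor is ln(odds) of MAS.
4. Scores scale the log-odds: Score = A − B·ln(odds), with B = PD0/ln 2 and
   A = P0 + B·ln(odds0). PD0 is the score change per doubling of the odds,
   P0 the baseline score at the reference odds0. With odds0 = 1/19, P0 = 70
   and PD0 = 4.14 this gives A = 52.41 and B = 5.97: MAS-typical patients
   land at *low* scores.
5. Per-bin integer points are −B·weight·WOE plus an equal share of the base
   points A − B·intercept; a patient's total score is the sum over their bins.
6. The decision threshold is the score maximizing the Kolmogorov-Smirnov
   separation between the two classes' cumulative score distributions; a
   score at or below the threshold is called MAS.
7. Gaussian kernel density estimates of the two classes' score distributions
   give the disease risk of a unit score interval, from which five risk bands
   (extremely high … extremely low) are cut at the 95/75/25/5% risk levels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .synth import CohortTable

__all__ = [
    "BinStats",
    "ScoreScaling",
    "ScoreBands",
    "ScorecardModel",
    "RiskFunction",
    "chimerge_bin",
    "woe_table",
    "fit_woe_lr",
    "scaling_coeffs",
    "assemble_points",
    "ks_threshold",
    "kde_risk",
    "band_thresholds",
    "score_patient",
    "build_scorecard",
]

BAND_LABELS = ("extremely_high", "high", "normal", "low", "extremely_low")
DEFAULT_LEVELS = (0.95, 0.75, 0.25, 0.05)


# --------------------------------------------------------------------------
# binning

@dataclass
class BinStats:
    """Supervised bins of one feature with class shares and WOE.

    ``edges`` are interior cut points; bin i covers (edges[i-1], edges[i]]
    with open terminal bins, so any real value maps to exactly one bin.
    """

    feature: str
    edges: list[float]
    n_neg: list[int] = field(default_factory=list)   # SLE count per bin
    n_pos: list[int] = field(default_factory=list)   # MAS count per bin
    pct_neg: list[float] = field(default_factory=list)  # SLE% share per bin
    pct_pos: list[float] = field(default_factory=list)  # MAS% share per bin
    woe: list[float] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def assign(self, x) -> np.ndarray:
        """Bin index per value; values beyond the data range fall into the
        nearest terminal bin."""
        return np.searchsorted(self.edges, np.asarray(x, float), side="left")

    def interval_label(self, i: int) -> str:
        lo = "-inf" if i == 0 else f"{self.edges[i - 1]:g}"
        hi = "+inf" if i == len(self.edges) else f"{self.edges[i]:g}"
        return f"({lo}, {hi}]"


def _pair_chi2(n_neg: Sequence[int], n_pos: Sequence[int], i: int) -> tuple[float, float]:
    """Chi-square statistic and p-value for adjacent bins i, i+1 (2x2 table,
    no continuity correction; cells with zero expectation contribute 0)."""
    obs = np.array([[n_neg[i], n_pos[i]], [n_neg[i + 1], n_pos[i + 1]]], float)
    total = obs.sum()
    if total == 0:
        return 0.0, 1.0
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
    stat = float(terms.sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def _merge(edges: list, n_neg: list, n_pos: list, i: int) -> None:
    del edges[i]
    n_neg[i] += n_neg.pop(i + 1)
    n_pos[i] += n_pos.pop(i + 1)


def chimerge_bin(values, labels, n_prebins: int = 20, alpha: float = 0.05,
                 min_bins: int = 3, max_bins: int = 8,
                 prebin: str = "quantile", rule: str = "standard") -> BinStats:
    """Bottom-up chi-square binning of one continuous feature.

    Starts from ``n_prebins`` pre-bins (quantile by default, ``prebin=
    "width"`` for equal-width), then repeatedly merges the adjacent pair of
    bins whose class composition is most similar (smallest chi-square) while
    that pair does not differ significantly (p >= alpha) or while more than
    ``max_bins`` remain; merging stops when every adjacent pair differs at
    p < alpha or ``min_bins`` is reached. Empty bins are always absorbed.

    ``rule="literal"`` instead merges the pair with the largest chi-square
    among those with p < alpha — an occasionally printed inversion of
    ChiMerge that fuses the most *different* bins; provided for comparison.
    """
    x = np.asarray(values, float)
    y = np.asarray(labels, int)
    if np.isnan(x).any():
        raise ValueError("values must be complete (impute first)")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError("need at least 2 distinct values to bin")

    if len(distinct) <= max(min_bins, 2):
        edges = [float(v) for v in distinct[:-1]]  # one bin per distinct value
    else:
        if prebin == "quantile":
            qs = np.quantile(x, np.linspace(0, 1, n_prebins + 1)[1:-1])
        elif prebin == "width":
            qs = np.linspace(x.min(), x.max(), n_prebins + 1)[1:-1]
        else:
            raise ValueError(f"unknown prebin mode {prebin!r}")
        edges = sorted(set(float(v) for v in qs if x.min() <= v < x.max()))

    idx = np.searchsorted(edges, x, side="left")
    k = len(edges) + 1
    n_neg = [int(np.sum((idx == i) & (y == 0))) for i in range(k)]
    n_pos = [int(np.sum((idx == i) & (y == 1))) for i in range(k)]

    # absorb empty bins into their left neighbour (right neighbour for bin 0)
    i = 0
    while i < len(n_neg) and len(n_neg) > 1:
        if n_neg[i] + n_pos[i] == 0:
            _merge(edges, n_neg, n_pos, max(i - 1, 0))
            i = 0
        else:
            i += 1

    while len(n_neg) > min_bins:
        pairs = [_pair_chi2(n_neg, n_pos, i) for i in range(len(n_neg) - 1)]
        if rule == "standard":
            i_best = int(np.argmin([c for c, _ in pairs]))
            stat, p = pairs[i_best]
            if p >= alpha or len(n_neg) > max_bins:
                _merge(edges, n_neg, n_pos, i_best)
            else:
                break
        elif rule == "literal":
            cand = [(c, i) for i, (c, p) in enumerate(pairs) if p < alpha]
            if cand:
                _, i_best = max(cand)
            elif len(n_neg) > max_bins:
                i_best = int(np.argmax([c for c, _ in pairs]))
            else:
                break
            _merge(edges, n_neg, n_pos, i_best)
        else:
            raise ValueError(f"unknown merge rule {rule!r}")

    return BinStats(feature="", edges=edges, n_neg=n_neg, n_pos=n_pos)


# --------------------------------------------------------------------------
# weight of evidence

def woe_table(edges: Sequence[float], values, labels,
              smoothing: float = 0.5, feature: str = "") -> BinStats:
    """Per-bin class counts, shares and WOE = ln(SLE% / MAS%).

    Zero counts receive additive smoothing of ``smoothing`` so every WOE is
    finite; class shares are renormalized afterwards. Bins empty in both
    classes are merged into their left neighbour with a warning.
    """
    x = np.asarray(values, float)
    y = np.asarray(labels, int)
    edges = [float(e) for e in edges]
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("edges must be strictly increasing")
    idx = np.searchsorted(edges, x, side="left")
    k = len(edges) + 1
    n_neg = [int(np.sum((idx == i) & (y == 0))) for i in range(k)]
    n_pos = [int(np.sum((idx == i) & (y == 1))) for i in range(k)]
    i = 0
    while i < len(n_neg) and len(n_neg) > 1:
        if n_neg[i] + n_pos[i] == 0:
            warnings.warn(f"bin {i} of {feature or 'feature'} empty in both classes; merged")
            _merge(edges, n_neg, n_pos, max(i - 1, 0))
            i = 0
        else:
            i += 1
    sm_neg = np.array([c if c > 0 else smoothing for c in n_neg], float)
    sm_pos = np.array([c if c > 0 else smoothing for c in n_pos], float)
    pct_neg = sm_neg / sm_neg.sum()
    pct_pos = sm_pos / sm_pos.sum()
    woe = np.log(pct_neg / pct_pos)
    return BinStats(feature=feature, edges=edges, n_neg=n_neg, n_pos=n_pos,
                    pct_neg=[float(v) for v in pct_neg],
                    pct_pos=[float(v) for v in pct_pos],
                    woe=[float(v) for v in woe])


def fit_woe_lr(woe_frame, labels, C: float = 1.0) -> tuple[float, dict[str, float]]:
    """Logistic regression on WOE-encoded features, MAS as the positive
    class; a mild L2 penalty (strength 1/C) stabilizes collinear WOE columns.
    Returns (intercept, {feature: weight})."""
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    cols = list(woe_frame.columns)
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=5000)
    model.fit(woe_frame.to_numpy(float), y)
    if int(np.max(model.n_iter_)) >= 5000:
        raise RuntimeError(
            f"WOE-logistic fit did not converge within {int(np.max(model.n_iter_))} iterations")
    return float(model.intercept_[0]), {c: float(b) for c, b in zip(cols, model.coef_.ravel())}


# --------------------------------------------------------------------------
# score scaling

@dataclass(frozen=True)
class ScoreScaling:
    odds0: float
    P0: float
    PD0: float
    A: float
    B: float


def scaling_coeffs(odds0: float, P0: float, PD0: float) -> ScoreScaling:
    """Score transformation Score = A − B·ln(odds): B = PD0/ln 2 (points per
    doubling of the odds) and A = P0 + B·ln(odds0) (so odds0 maps to P0)."""
    if odds0 <= 0:
        raise ValueError("odds0 must be positive")
    if PD0 <= 0:
        raise ValueError("PD0 must be positive")
    B = PD0 / np.log(2.0)
    A = P0 + B * np.log(odds0)
    return ScoreScaling(odds0=odds0, P0=P0, PD0=PD0, A=float(A), B=float(B))


# --------------------------------------------------------------------------
# assembled card

@dataclass
class ScoreBands:
    """Score intervals mapped to disease-risk strata.

    ``thresholds`` maps each risk level to the highest score whose
    unit-interval risk still reaches that level; risk is non-increasing in
    score, so extremely-high risk sits at the bottom of the score range.
    """

    thresholds: dict[float, int]
    score_range: tuple[int, int] = (0, 100)

    def intervals(self) -> dict[str, tuple[int, int]]:
        lo, hi = self.score_range
        t = [self.thresholds[lv] for lv in sorted(self.thresholds, reverse=True)]
        cuts = [lo - 1, *t, hi]
        return {lab: (cuts[i] + 1, cuts[i + 1])
                for i, lab in enumerate(BAND_LABELS)}

    def band_of(self, score: float) -> str:
        s = min(max(score, self.score_range[0]), self.score_range[1])
        for lab, (lo, hi) in self.intervals().items():
            if lo <= s <= hi:
                return lab
        return BAND_LABELS[-1]


@dataclass
class ScorecardModel:
    scaling: ScoreScaling
    intercept: float
    coefficients: dict[str, float]
    bins: dict[str, BinStats]
    points: dict[str, list[int]]
    base_points: float           # A − B·intercept, before distribution
    threshold: int | None = None
    ks: float | None = None
    bands: ScoreBands | None = None
    normal_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return sorted(self.coefficients)

    def woe_of(self, record: Mapping[str, float]) -> dict[str, float]:
        return {f: self.bins[f].woe[int(self.bins[f].assign([record[f]])[0])]
                for f in self.features}

    def linear_predictor(self, record: Mapping[str, float]) -> float:
        w = self.woe_of(record)
        return self.intercept + sum(self.coefficients[f] * w[f] for f in self.features)

    def score_unrounded(self, record: Mapping[str, float]) -> float:
        return self.scaling.A - self.scaling.B * self.linear_predictor(record)

    def score(self, record: Mapping[str, float]) -> int:
        total = 0
        for f in self.features:
            i = int(self.bins[f].assign([record[f]])[0])
            total += self.points[f][i]
        return total

    def score_cohort(self, cohort: CohortTable) -> np.ndarray:
        out = np.zeros(cohort.n_patients, float)
        for f in self.features:
            idx = self.bins[f].assign(cohort.frame[f].to_numpy(float))
            idx = np.clip(idx, 0, len(self.points[f]) - 1)
            out += np.asarray(self.points[f])[idx]
        return out

    # ---- serialization ----

    def to_json(self, path) -> None:
        d = {
            "scaling": self.scaling.__dict__,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "bins": {f: b.__dict__ for f, b in self.bins.items()},
            "points": self.points,
            "base_points": self.base_points,
            "threshold": self.threshold,
            "ks": self.ks,
            "bands": None if self.bands is None else {
                "thresholds": {str(k): v for k, v in self.bands.thresholds.items()},
                "score_range": list(self.bands.score_range)},
            "normal_ranges": {k: list(v) for k, v in self.normal_ranges.items()},
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScorecardModel":
        with open(path) as fh:
            d = json.load(fh)
        bands = None
        if d["bands"] is not None:
            bands = ScoreBands({float(k): int(v) for k, v in d["bands"]["thresholds"].items()},
                               tuple(d["bands"]["score_range"]))
        return cls(
            scaling=ScoreScaling(**d["scaling"]),
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            bins={f: BinStats(**b) for f, b in d["bins"].items()},
            points={f: [int(p) for p in v] for f, v in d["points"].items()},
            base_points=d["base_points"],
            threshold=d["threshold"],
            ks=d["ks"],
            bands=bands,
            normal_ranges={k: tuple(v) for k, v in d["normal_ranges"].items()},
        )

    def to_card_rows(self) -> list[dict]:
        """Human-readable card: one row per (feature, bin, points)."""
        rows = []
        for f in self.features:
            b = self.bins[f]
            for i in range(b.n_bins):
                rows.append({"feature": f, "bin": b.interval_label(i),
                             "woe": round(b.woe[i], 4), "points": self.points[f][i]})
        return rows


def assemble_points(intercept: float, coefficients: dict[str, float],
                    bins: dict[str, BinStats], scaling: ScoreScaling,
                    normal_ranges: dict[str, tuple[float, float]] | None = None
                    ) -> ScorecardModel:
    """Turn the WOE-logistic fit into integer per-bin points.

    Points for bin i of feature j are round(−B·w_j·WOE_ij + base/p) with the
    base points A − B·intercept shared equally across the p active features;
    the unrounded total equals A − B·ln(odds) exactly, so rounding error is
    bounded by half a point per feature.
    """
    for f in coefficients:
        if f not in bins:
            raise ValueError(f"feature {f!r} present in model but absent from bins")
    p = len(coefficients)
    base = scaling.A - scaling.B * intercept
    points = {
        f: [int(round(-scaling.B * coefficients[f] * w + base / p))
            for w in bins[f].woe]
        for f in coefficients
    }
    return ScorecardModel(scaling=scaling, intercept=intercept,
                          coefficients=dict(coefficients),
                          bins={f: bins[f] for f in coefficients},
                          points=points, base_points=float(base),
                          normal_ranges=dict(normal_ranges or {}))


# --------------------------------------------------------------------------
# threshold and risk bands

def ks_threshold(scores, labels) -> tuple[float, float]:
    """KS statistic and threshold over candidate scores in ascending order.

    KS is the maximum |CDF_MAS(s) − CDF_SLE(s)|; the threshold is the lowest
    score attaining it. Decision rule: score <= threshold predicts MAS.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    cand = np.unique(s)
    cdf_pos = np.array([np.mean(s[y == 1] <= c) for c in cand])
    cdf_neg = np.array([np.mean(s[y == 0] <= c) for c in cand])
    diff = np.abs(cdf_pos - cdf_neg)
    # lowest score attaining the maximum; ties compared with a float guard
    best = float(np.max(diff))
    i = int(np.nonzero(diff >= best - 1e-12)[0][0])
    return float(diff[i]), float(cand[i])


class RiskFunction:
    """Disease risk over unit score intervals from class-conditional Gaussian
    KDEs: risk(s) = π·∫f₊ / (π·∫f₊ + (1−π)·∫f₋) over [s−½, s+½]."""

    def __init__(self, scores_pos, scores_neg, prior_pos: float | None = None,
                 bandwidth=None):
        sp = np.asarray(scores_pos, float)
        sn = np.asarray(scores_neg, float)
        if len(sp) < 5 or len(sn) < 5:
            raise ValueError("need at least 5 scores per class")
        self.prior_pos = (len(sp) / (len(sp) + len(sn))
                          if prior_pos is None else float(prior_pos))
        bw = bandwidth if bandwidth is not None else "silverman"
        try:
            self.kde_pos = stats.gaussian_kde(sp, bw_method=bw)
            self.kde_neg = stats.gaussian_kde(sn, bw_method=bw)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "degenerate (constant) score set; supply an explicit bandwidth") from exc

    def interval_mass(self, s: float) -> tuple[float, float]:
        lo, hi = s - 0.5, s + 0.5
        return (float(self.kde_pos.integrate_box_1d(lo, hi)),
                float(self.kde_neg.integrate_box_1d(lo, hi)))

    def __call__(self, s: float) -> float:
        mp, mn = self.interval_mass(s)
        num = self.prior_pos * mp
        den = num + (1.0 - self.prior_pos) * mn
        if den <= 0.0:
            return 0.5  # no mass from either class: uninformative
        return num / den


def kde_risk(scores_pos, scores_neg, prior_pos: float | None = None,
             bandwidth=None) -> RiskFunction:
    """Fit class-conditional Gaussian KDEs (Silverman bandwidth by default)
    and return the unit-interval posterior risk function."""
    return RiskFunction(scores_pos, scores_neg, prior_pos, bandwidth)


def band_thresholds(risk: RiskFunction, levels: Sequence[float] = DEFAULT_LEVELS,
                    score_range: tuple[int, int] = (0, 100),
                    monotone_tol: float = 1e-6) -> ScoreBands:
    """For each risk level, the highest integer score whose unit-interval
    risk still reaches it; the four thresholds cut the score range into the
    five labelled bands. Raises if a level is never attained or the risk
    rises with score anywhere beyond ``monotone_tol``."""
    lo, hi = score_range
    grid = np.arange(lo, hi + 1)
    r = np.array([risk(float(s)) for s in grid])
    rises = np.where(np.diff(r) > monotone_tol)[0]
    if len(rises):
        a, b = grid[rises[0]], grid[rises[-1] + 1]
        raise ValueError(f"risk is not non-increasing on scores {a}..{b}; "
                         "bands would be inconsistent")
    thresholds: dict[float, int] = {}
    for lv in sorted(levels, reverse=True):
        attained = np.where(r >= lv)[0]
        if len(attained) == 0:
            raise ValueError(f"risk level {lv:.0%} is never attained on the score grid")
        thresholds[lv] = int(grid[attained[-1]])
    t = list(thresholds.values())
    # ties are allowed: when the risk transition is sharper than one score
    # point, adjacent levels quantize to the same cut and a band is empty
    if any(t[i] > t[i + 1] for i in range(len(t) - 1)):
        raise ValueError(f"band thresholds are out of order: {thresholds}")
    return ScoreBands(thresholds=thresholds, score_range=score_range)


def score_patient(card: ScorecardModel, record: Mapping[str, float],
                  risk: RiskFunction | None = None) -> dict:
    """Score one patient from raw feature values.

    Returns the integer total score, the [0, 100]-clamped presentation score,
    the risk band label, the unit-interval risk (when a risk function is
    attached), and per-feature flags for values outside the clinical normal
    range. Values beyond all bin edges fall into the nearest terminal bin.
    """
    missing = [f for f in card.features if f not in record or record[f] is None
               or (isinstance(record[f], float) and np.isnan(record[f]))]
    if missing:
        raise ValueError("missing required features: " + ", ".join(sorted(missing)))
    total = card.score(record)
    lo, hi = (card.bands.score_range if card.bands is not None else (0, 100))
    clamped = int(min(max(total, lo), hi))
    out = {
        "score": int(total),
        "score_clamped": clamped,
        "band": card.bands.band_of(clamped) if card.bands is not None else None,
        "risk": None if risk is None else float(risk(float(clamped))),
        "predicted": None if card.threshold is None
        else ("MAS" if total <= card.threshold else "SLE"),
        "out_of_range": sorted(
            f for f, (rlo, rhi) in card.normal_ranges.items()
            if f in record and not rlo <= record[f] <= rhi),
    }
    return out


# --------------------------------------------------------------------------
# end-to-end construction

def build_scorecard(cohort: CohortTable,
                    odds0: float = 1.0 / 19.0, P0: float = 70.0, PD0: float = 4.14,
                    n_prebins: int = 20, alpha: float = 0.05,
                    min_bins: int = 3, max_bins: int = 8,
                    levels: Sequence[float] = DEFAULT_LEVELS,
                    bandwidth=None, C: float = 1.0,
                    normal_ranges: dict[str, tuple[float, float]] | None = None,
                    rule: str = "standard",
                    ) -> tuple[ScorecardModel, RiskFunction]:
    """Fit the full card on a complete training cohort of raw feature values:
    bin, WOE-encode, fit the logistic model, scale to points, pick the KS
    threshold and cut the KDE risk bands."""
    import pandas as pd

    bins: dict[str, BinStats] = {}
    for f in cohort.frame.columns:
        x = cohort.frame[f].to_numpy(float)
        if len(np.unique(x)) <= 2:
            edges = [float(np.mean(np.unique(x)))] if len(np.unique(x)) == 2 else []
        else:
            edges = chimerge_bin(x, cohort.label, n_prebins=n_prebins, alpha=alpha,
                                 min_bins=min_bins, max_bins=max_bins, rule=rule).edges
        bins[f] = woe_table(edges, x, cohort.label, feature=f)

    woe_frame = pd.DataFrame({
        f: np.asarray(bins[f].woe)[bins[f].assign(cohort.frame[f].to_numpy(float))]
        for f in sorted(cohort.frame.columns)})
    intercept, coefs = fit_woe_lr(woe_frame, cohort.label, C=C)
    scaling = scaling_coeffs(odds0, P0, PD0)
    card = assemble_points(intercept, coefs, bins, scaling, normal_ranges)

    scores = card.score_cohort(cohort)
    card.ks, thr = ks_threshold(scores, cohort.label)
    card.threshold = int(thr)
    risk = kde_risk(scores[cohort.label == 1], scores[cohort.label == 0],
                    bandwidth=bandwidth)
    card.bands = band_thresholds(risk, levels=levels)
    return card, risk
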