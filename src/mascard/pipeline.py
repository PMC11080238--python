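"""End-to-end reproducible pipeline: simulate → preprocess → select → train →
evaluate → scorecard → report.

A run is fully determined by its configuration and master seed: every stage
draws its randomness from a named substream of the master seed and writes
plain CSV/JSON artifacts into the run directory, together with a manifest
holding the configuration hash. Re-running with ``resume=True`` regenerates
only missing artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import models as mdl
from . import preprocess as prep
from . import scorecard as sc
from .synth import CohortConfig, CohortTable, default_feature_specs, spec_sidecar

__all__ = ["PipelineConfig", "run_pipeline", "report"]

STAGES = ("simulate", "preprocess", "select", "train", "scorecard", "report")


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    n_neg: int = 94
    n_pos: int = 94
    n_noise: int = 20
    external_shift: float = 0.25
    external_scale: float = 1.1
    test_fraction: float = 0.2
    low_threshold: float = 0.05
    high_threshold: float = 0.20
    pearson_threshold: float = 0.8
    vif_threshold: float = 10.0
    lasso_folds: int = 5
    odds0: float = 1.0 / 19.0
    P0: float = 70.0
    PD0: float = 4.14
    chimerge_alpha: float = 0.05
    min_bins: int = 3
    max_bins: int = 8
    band_levels: tuple[float, ...] = (0.95, 0.75, 0.25, 0.05)
    kde_bandwidth: float | None = None
    prob_threshold: float = 0.5

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "band_levels" in d:
            d["band_levels"] = tuple(d["band_levels"])
        return cls(**d)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(master: int, stage: str) -> int:
    """Named substream seed below 2^31, derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _outputs(run_dir: Path) -> dict[str, list[Path]]:
    return {
        "simulate": [run_dir / "cohort.csv", run_dir / "external.csv",
                     run_dir / "specs.json"],
        "preprocess": [run_dir / "train_raw.csv", run_dir / "test_raw.csv",
                       run_dir / "external_raw.csv", run_dir / "train_z.csv",
                       run_dir / "test_z.csv", run_dir / "external_z.csv",
                       run_dir / "scaler.json", run_dir / "imputation.json"],
        "select": [run_dir / "selection.json"],
        "train": [run_dir / "metrics.csv", run_dir / "metrics.json"],
        "scorecard": [run_dir / "scorecard.json", run_dir / "card.csv",
                      run_dir / "ks_curve.csv", run_dir / "risk_curve.csv",
                      run_dir / "bands.json"],
        "report": [run_dir / "report.md"],
    }


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(json.dumps({"stage": stage, "error": str(exc)}))
        self.stage = stage


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Execute every stage, writing artifacts and a manifest into
    ``config.out_dir``; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    outputs = _outputs(run_dir)
    funcs = {"simulate": _stage_simulate, "preprocess": _stage_preprocess,
             "select": _stage_select, "train": _stage_train,
             "scorecard": _stage_scorecard, "report": _stage_report}
    manifest = {"config": dataclasses.asdict(config), "config_hash": config.digest(),
                "seeds": {s: stage_seed(config.seed, s) for s in STAGES},
                "stages_run": []}
    for stage in STAGES:
        if resume and all(p.exists() for p in outputs[stage]):
            continue
        try:
            funcs[stage](config, run_dir)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        manifest["stages_run"].append(stage)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return run_dir


# --------------------------------------------------------------------------
# stages

def _stage_simulate(config: PipelineConfig, run_dir: Path) -> None:
    cc = CohortConfig(n_neg=config.n_neg, n_pos=config.n_pos,
                      n_noise=config.n_noise,
                      seed=stage_seed(config.seed, "simulate"))
    from .synth import generate_cohort, generate_external_cohort
    generate_cohort(cc).to_csv(run_dir / "cohort.csv")
    ext_cc = dataclasses.replace(cc, seed=stage_seed(config.seed, "simulate-external"))
    generate_external_cohort(ext_cc, location_shift=config.external_shift,
                             scale=config.external_scale).to_csv(run_dir / "external.csv")
    (run_dir / "specs.json").write_text(spec_sidecar(cc))


def _split_train_test(cohort: CohortTable, test_fraction: float, seed: int
                      ) -> tuple[CohortTable, CohortTable]:
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in (0, 1):
        idx = np.where(cohort.label == cls)[0]
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(rng.choice(idx, size=n_test, replace=False))
    test_mask = np.zeros(cohort.n_patients, bool)
    test_mask[test_idx] = True

    def take(mask):
        return CohortTable(cohort.frame[mask].reset_index(drop=True),
                           cohort.label[mask],
                           None if cohort.outcome is None
                           else cohort.outcome[mask].reset_index(drop=True))
    return take(~test_mask), take(test_mask)


def _stage_preprocess(config: PipelineConfig, run_dir: Path) -> None:
    specs = default_feature_specs()
    seed = stage_seed(config.seed, "preprocess")
    cohort = CohortTable.from_csv(run_dir / "cohort.csv")
    policy = prep.ImputationPolicy(low_threshold=config.low_threshold,
                                   high_threshold=config.high_threshold, seed=seed)
    completed, imp_report = prep.impute(cohort, policy)
    audit = prep.audit_shift(cohort, completed)
    flagged = prep.derive_range_flags(completed, specs)
    _, processed = prep.flag_outliers_iqr(flagged)
    train, test = _split_train_test(processed, config.test_fraction, seed)

    # constant columns cannot be Z-scored; drop them explicitly everywhere
    constant = [c for c in train.frame.columns if train.frame[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant columns before scaling: {constant}")
    keep = [c for c in train.frame.columns if c not in constant]
    train, test = train.select(keep), test.select(keep)

    scaler = prep.zscore_fit(train)
    # external validation: per-patient exclusion of missingness, then the
    # previously fitted Z-score model is reapplied, never re-estimated
    external = CohortTable.from_csv(run_dir / "external.csv")
    complete_rows = ~external.frame.isna().any(axis=1).to_numpy()
    external = CohortTable(external.frame[complete_rows].reset_index(drop=True),
                           external.label[complete_rows],
                           None if external.outcome is None
                           else external.outcome[complete_rows].reset_index(drop=True))
    external = prep.derive_range_flags(external, specs).select(keep)

    train.to_csv(run_dir / "train_raw.csv")
    test.to_csv(run_dir / "test_raw.csv")
    external.to_csv(run_dir / "external_raw.csv")
    prep.zscore_apply(train, scaler).to_csv(run_dir / "train_z.csv")
    prep.zscore_apply(test, scaler).to_csv(run_dir / "test_z.csv")
    prep.zscore_apply(external, scaler).to_csv(run_dir / "external_z.csv")
    scaler.to_json(run_dir / "scaler.json")
    with open(run_dir / "imputation.json", "w") as fh:
        json.dump({"methods": imp_report, "audit_p": audit.p_values,
                   "audit_passed": audit.passed, "audit_skipped": audit.skipped},
                  fh, indent=2)


def _stage_select(config: PipelineConfig, run_dir: Path) -> None:
    train = CohortTable.from_csv(run_dir / "train_z.csv")
    seed = stage_seed(config.seed, "select")
    reduced, pearson_removed = feat.pearson_filter(train, config.pearson_threshold)
    reduced, vif_removed = feat.vif_filter(reduced, config.vif_threshold)
    rep = feat.lasso_select(reduced, k_folds=config.lasso_folds, seed=seed)
    with open(run_dir / "selection.json", "w") as fh:
        json.dump({
            "pearson_removed": [{"removed": a, "kept": b, "abs_r": r}
                                for a, b, r in pearson_removed],
            "vif_removed": [{"removed": a, "vif": v} for a, v in vif_removed],
            "lambda_grid": rep.lambda_grid, "cv_deviance": rep.cv_deviance,
            "best_lambda": rep.best_lambda, "selected": rep.selected,
            "coefficients": rep.coefficients,
        }, fh, indent=2)


_FAMILY_LABEL = {"l2_logistic": "LR", "random_forest": "RF",
                 "svm": "SVM", "gradient_boosting": "XGBoost"}


def _stage_train(config: PipelineConfig, run_dir: Path) -> None:
    with open(run_dir / "selection.json") as fh:
        selected = json.load(fh)["selected"]
    seed = stage_seed(config.seed, "train")
    splits = {name: CohortTable.from_csv(run_dir / f"{name}_z.csv").select(selected)
              for name in ("train", "test", "external")}
    rows = []
    fitted = {}
    for family, spec in mdl.default_model_specs(seed).items():
        model, params = mdl.grid_search_fit(splits["train"], spec)
        fitted[_FAMILY_LABEL[family]] = model
        loo = mdl.loo_validate(splits["train"], spec, params,
                               threshold=config.prob_threshold)
        rows.append({"model": _FAMILY_LABEL[family], "split": "validation",
                     "auc": loo.auc, "f1": loo.f1, "f2": loo.f2,
                     "tp": loo.tp, "fp": loo.fp, "tn": loo.tn, "fn": loo.fn})
    table = mdl.evaluate_suite(fitted, {"test": splits["test"],
                                        "external": splits["external"]},
                               threshold=config.prob_threshold)
    table = pd.concat([pd.DataFrame(rows), table], ignore_index=True)
    table.to_csv(run_dir / "metrics.csv", index=False)
    table.to_json(run_dir / "metrics.json", orient="records", indent=2)


def _scorecard_metrics(card: sc.ScorecardModel, cohort: CohortTable) -> dict:
    scores = card.score_cohort(cohort)
    y = cohort.label
    auc = mdl.roc_auc(-scores, y)  # low score means MAS-typical
    pred = (scores <= card.threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = mdl.f_beta(precision, recall, 1.0)
        f2 = mdl.f_beta(precision, recall, 2.0)
    return {"auc": auc, "f1": f1, "f2": f2, "tp": tp, "fp": fp, "tn": tn, "fn": fn}


def _stage_scorecard(config: PipelineConfig, run_dir: Path) -> None:
    with open(run_dir / "selection.json") as fh:
        selected = json.load(fh)["selected"]
    specs = {s.name: s for s in default_feature_specs()}
    ranges = {f: specs[f].normal_range for f in selected
              if f in specs and specs[f].normal_range is not None}
    splits = {name: CohortTable.from_csv(run_dir / f"{name}_raw.csv").select(selected)
              for name in ("train", "test", "external")}
    card, risk = sc.build_scorecard(
        splits["train"], odds0=config.odds0, P0=config.P0, PD0=config.PD0,
        alpha=config.chimerge_alpha, min_bins=config.min_bins,
        max_bins=config.max_bins, levels=config.band_levels,
        bandwidth=config.kde_bandwidth, normal_ranges=ranges)
    card.to_json(run_dir / "scorecard.json")
    pd.DataFrame(card.to_card_rows()).to_csv(run_dir / "card.csv", index=False)

    scores = card.score_cohort(splits["train"])
    cand = np.unique(scores)
    ks_rows = pd.DataFrame({
        "score": cand,
        "cdf_mas": [np.mean(scores[splits["train"].label == 1] <= c) for c in cand],
        "cdf_sle": [np.mean(scores[splits["train"].label == 0] <= c) for c in cand]})
    ks_rows["diff"] = (ks_rows["cdf_mas"] - ks_rows["cdf_sle"]).abs()
    ks_rows.to_csv(run_dir / "ks_curve.csv", index=False)

    grid = np.arange(card.bands.score_range[0], card.bands.score_range[1] + 1)
    pd.DataFrame({
        "score": grid,
        "density_mas": [risk.kde_pos(float(s))[0] for s in grid],
        "density_sle": [risk.kde_neg(float(s))[0] for s in grid],
        "risk": [risk(float(s)) for s in grid],
    }).to_csv(run_dir / "risk_curve.csv", index=False)

    with open(run_dir / "bands.json", "w") as fh:
        json.dump({"threshold": card.threshold, "ks": card.ks,
                   "bands": {k: list(v) for k, v in card.bands.intervals().items()}},
                  fh, indent=2)

    # append the scorecard rows to the metric table (validation = training pool)
    table = pd.read_csv(run_dir / "metrics.csv")
    table = table[table["model"] != "ScoreCard"]
    extra = []
    for split_name, split in (("validation", splits["train"]),
                              ("test", splits["test"]),
                              ("external", splits["external"])):
        extra.append({"model": "ScoreCard", "split": split_name,
                      **_scorecard_metrics(card, split)})
    table = pd.concat([table, pd.DataFrame(extra)], ignore_index=True)
    table.to_csv(run_dir / "metrics.csv", index=False)
    table.to_json(run_dir / "metrics.json", orient="records", indent=2)


def _stage_report(config: PipelineConfig, run_dir: Path) -> None:
    (run_dir / "report.md").write_text(report(run_dir))


def report(run_dir) -> str:
    """Deterministic markdown summary of a finished run: metric table,
    selected features, scorecard, threshold and bands."""
    run_dir = Path(run_dir)
    missing = [s for s, paths in _outputs(run_dir).items()
               if s != "report" and not all(p.exists() for p in paths)]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing stages: {missing}")
    with open(run_dir / "selection.json") as fh:
        sel = json.load(fh)
    with open(run_dir / "bands.json") as fh:
        bands = json.load(fh)
    metrics = pd.read_csv(run_dir / "metrics.csv")
    card = pd.read_csv(run_dir / "card.csv")
    lines = ["# Diagnostic pipeline report", ""]
    lines += ["## Model performance (AUC / F1 / F2 per split)", "",
              metrics.round(4).to_csv(index=False).strip(), ""]
    lines += ["## Selected features", "",
              ", ".join(sel["selected"]),
              f"\nbest lambda: {sel['best_lambda']:.6g}", ""]
    lines += ["## Scorecard", "", card.to_csv(index=False).strip(), ""]
    lines += [f"## Decision threshold: {bands['threshold']} (KS = {bands['ks']:.4f})", ""]
    lines += ["## Risk bands", ""]
    for lab, (lo, hi) in bands["bands"].items():
        lines.append(f"- {lab}: {lo}–{hi}")
    lines.append("")
    return "\n".join(lines)
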