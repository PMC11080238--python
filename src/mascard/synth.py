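"""Synthetic SLE / MAS-secondary-to-SLE cohort generation.

No public dataset exists for the secondary-MAS diagnostic problem, so this
module generates balanced case-control cohorts with the statistical structure
the downstream pipeline assumes: 13 informative clinical predictors whose
class-conditional location shifts follow the clinically reported directions
(higher ferritin, temperature, fever duration, CRP, LDH, TG and PT in MAS;
lower fibrinogen, HDL, serum sodium and TNF-α), a configurable block of
uninformative nuisance features, tiered missing-completely-at-random entries,
and an in-hospital mortality outcome confined to the MAS group.

Heavy-tailed analytes (ferritin, LDH, CRP, TG, fever duration) are log-normal;
the remaining continuous features are Gaussian, truncated at a physiological
floor where the assay cannot be negative. Binary composites (pancytopenia,
liver damage) are Bernoulli by default; ``raw_lineage=True`` instead emits the
five underlying analytes (HB, PLT, WBC, ALT, AST) so composite construction
can be exercised downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dist",
    "FeatureSpec",
    "CohortConfig",
    "CohortTable",
    "ConfigError",
    "default_feature_specs",
    "raw_lineage_ranges",
    "generate_cohort",
    "generate_external_cohort",
    "MAS_MORTALITY",
]

#: deaths observed in the MAS group of the 94+94 study cohort (none in SLE)
MAS_MORTALITY = (15, 94)

LABEL_COLUMN = "diagnosis"
LABEL_NAMES = {0: "SLE", 1: "MAS"}


class ConfigError(ValueError):
    """Invalid cohort configuration; message names the offending field."""


@dataclass(frozen=True)
class Dist:
    """Class-conditional sampling distribution for one feature.

    family: "normal" (mean, sd), "lognormal" (mu, sigma of the log), or
    "bernoulli" (p,). ``floor`` truncates normal draws from below, for
    assays that cannot be negative.
    """

    family: str
    params: tuple[float, ...]
    floor: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal", "bernoulli"):
            raise ConfigError(f"Dist.family: unknown family {self.family!r}")
        if self.family == "bernoulli" and not 0.0 < self.params[0] < 1.0:
            raise ConfigError(f"Dist.params: Bernoulli p must be in (0,1), got {self.params[0]}")

    def mean(self) -> float:
        if self.family == "normal":
            return self.params[0]
        if self.family == "lognormal":
            mu, sigma = self.params
            return float(np.exp(mu + sigma**2 / 2.0))
        return self.params[0]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "normal":
            x = rng.normal(self.params[0], self.params[1], size=n)
            if self.floor is not None:
                x = np.maximum(x, self.floor)
            return x
        if self.family == "lognormal":
            return rng.lognormal(self.params[0], self.params[1], size=n)
        return rng.binomial(1, self.params[0], size=n).astype(float)


@dataclass(frozen=True)
class FeatureSpec:
    """Metadata for one simulated feature.

    ``normal_range`` is the clinical reference interval in the feature's own
    units; ``missing_rate`` is the MCAR fraction injected at generation time.
    """

    name: str
    kind: str  # "continuous" | "binary"
    units: str
    dist_neg: Dist
    dist_pos: Dist
    normal_range: tuple[float, float] | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ConfigError(f"FeatureSpec.kind: {self.kind!r} for {self.name}")
        if self.kind == "continuous":
            if self.normal_range is None:
                raise ConfigError(f"FeatureSpec.normal_range: required for continuous {self.name}")
            lo, hi = self.normal_range
            if not lo < hi:
                raise ConfigError(f"FeatureSpec.normal_range: lower >= upper for {self.name}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError(f"FeatureSpec.missing_rate: {self.missing_rate} for {self.name}")

    @property
    def informative(self) -> bool:
        return self.dist_neg != self.dist_pos

    def direction(self) -> int:
        """Sign of (MAS mean − SLE mean); 0 for uninformative features."""
        d = self.dist_pos.mean() - self.dist_neg.mean()
        return 0 if d == 0 else (1 if d > 0 else -1)


def _ln(median: float, sigma: float) -> tuple[float, float]:
    return (float(np.log(median)), sigma)


def default_feature_specs(raw_lineage: bool = False) -> list[FeatureSpec]:
    """The 13 informative predictors of the secondary-MAS diagnostic problem.

    Location shifts follow the reported clinical directions: MAS cases run
    hotter and longer fevers, with hyponatremia, hypertriglyceridemia, low
    HDL, high LDH, marked hyperferritinemia (MAS median well above the
    1,242.25 µg/L discriminating level), elevated CRP, hypofibrinogenemia,
    prolonged PT, *lower* TNF-α at admission, and frequent pancytopenia and
    liver damage.

    With ``raw_lineage=True`` the two Bernoulli composites are replaced by
    their five source analytes (HB, PLT, WBC, ALT, AST) so that composite
    construction from raw counts can be exercised.
    """
    specs = [
        FeatureSpec("max_temperature", "continuous", "°C",
                    Dist("normal", (37.9, 0.65)), Dist("normal", (39.4, 0.65)),
                    (36.0, 37.3), 0.0),
        FeatureSpec("fever_duration", "continuous", "days",
                    Dist("lognormal", _ln(3.4, 0.6)), Dist("lognormal", _ln(16.0, 0.6)),
                    (0.0, 7.0), 0.0),
        FeatureSpec("sodium", "continuous", "mmol/L",
                    Dist("normal", (140.2, 3.3)), Dist("normal", (132.5, 3.3)),
                    (137.0, 147.0), 0.02),
        FeatureSpec("TG", "continuous", "mmol/L",
                    Dist("lognormal", _ln(1.12, 0.38)), Dist("lognormal", _ln(3.0, 0.38)),
                    (0.3, 1.7), 0.03),
        FeatureSpec("HDL", "continuous", "mmol/L",
                    Dist("normal", (1.22, 0.27), floor=0.05),
                    Dist("normal", (0.59, 0.27), floor=0.05),
                    (1.0, 1.6), 0.03),
        FeatureSpec("LDH", "continuous", "U/L",
                    Dist("lognormal", _ln(210.0, 0.38)), Dist("lognormal", _ln(610.0, 0.38)),
                    (120.0, 250.0), 0.02),
        FeatureSpec("ferritin", "continuous", "µg/L",
                    Dist("lognormal", _ln(310.0, 0.80)), Dist("lognormal", _ln(3800.0, 0.80)),
                    (15.0, 400.0), 0.08),
        FeatureSpec("CRP", "continuous", "mg/L",
                    Dist("lognormal", _ln(5.5, 0.70)), Dist("lognormal", _ln(40.0, 0.70)),
                    (0.0, 8.0), 0.04),
        FeatureSpec("FIB", "continuous", "g/L",
                    Dist("normal", (3.80, 0.80), floor=0.1), Dist("normal", (1.95, 0.80), floor=0.1),
                    (2.0, 4.0), 0.02),
        FeatureSpec("PT", "continuous", "s",
                    Dist("normal", (10.9, 1.3)), Dist("normal", (14.0, 1.3)),
                    (9.0, 13.0), 0.02),
        FeatureSpec("TNF_alpha", "continuous", "pg/mL",
                    Dist("lognormal", _ln(29.0, 0.52)), Dist("lognormal", _ln(7.8, 0.52)),
                    (0.0, 8.1), 0.12),
    ]
    if raw_lineage:
        specs += _raw_lineage_specs()
    else:
        specs += [
            FeatureSpec("pancytopenia", "binary", "unitless",
                        Dist("bernoulli", (0.03,)), Dist("bernoulli", (0.75,)),
                        None, 0.01),
            FeatureSpec("liver_damage", "binary", "unitless",
                        Dist("bernoulli", (0.06,)), Dist("bernoulli", (0.78,)),
                        None, 0.01),
        ]
    return specs


def _raw_lineage_specs() -> list[FeatureSpec]:
    # Class-conditional locations chosen so three-lineage depression (MAS) and
    # transaminase elevation (MAS) occur at roughly the composite Bernoulli rates.
    return [
        FeatureSpec("HB", "continuous", "g/L",
                    Dist("normal", (112.0, 18.0)), Dist("normal", (86.0, 16.0)),
                    (115.0, 150.0), 0.0),
        FeatureSpec("PLT", "continuous", "10^9/L",
                    Dist("normal", (190.0, 70.0), floor=2.0),
                    Dist("normal", (80.0, 45.0), floor=2.0),
                    (125.0, 350.0), 0.0),
        FeatureSpec("WBC", "continuous", "10^9/L",
                    Dist("lognormal", _ln(5.6, 0.40)), Dist("lognormal", _ln(2.6, 0.50)),
                    (3.5, 9.5), 0.0),
        FeatureSpec("ALT", "continuous", "U/L",
                    Dist("lognormal", _ln(25.0, 0.60)), Dist("lognormal", _ln(80.0, 0.80)),
                    (7.0, 40.0), 0.0),
        FeatureSpec("AST", "continuous", "U/L",
                    Dist("lognormal", _ln(26.0, 0.55)), Dist("lognormal", _ln(110.0, 0.85)),
                    (13.0, 35.0), 0.0),
    ]


def raw_lineage_ranges() -> dict[str, tuple[float, float]]:
    """Clinical reference intervals of the five composite source analytes."""
    return {s.name: s.normal_range for s in _raw_lineage_specs()}


@dataclass(frozen=True)
class CohortConfig:
    n_neg: int = 94
    n_pos: int = 94
    features: tuple[FeatureSpec, ...] = field(
        default_factory=lambda: tuple(default_feature_specs()))
    n_noise: int = 20
    seed: int = 0
    mas_mortality: tuple[int, int] = MAS_MORTALITY

    def __post_init__(self) -> None:
        if self.n_neg < 2:
            raise ConfigError(f"CohortConfig.n_neg: must be >= 2, got {self.n_neg}")
        if self.n_pos < 2:
            raise ConfigError(f"CohortConfig.n_pos: must be >= 2, got {self.n_pos}")
        if self.n_noise < 0:
            raise ConfigError(f"CohortConfig.n_noise: must be >= 0, got {self.n_noise}")
        names = [s.name for s in self.features]
        if len(set(names)) != len(names):
            raise ConfigError("CohortConfig.features: duplicate feature names")


@dataclass
class CohortTable:
    """Per-patient feature matrix with label and missingness mask.

    ``frame`` holds numeric values with NaN marking absent entries; ``label``
    is 0 for SLE and 1 for MAS secondary to SLE; ``outcome`` optionally carries
    non-feature per-patient columns (e.g. the ``died`` indicator).
    """

    frame: pd.DataFrame
    label: np.ndarray
    outcome: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=int)
        if len(self.frame) != len(self.label):
            raise ValueError("frame and label length mismatch")

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def mask(self) -> np.ndarray:
        """Boolean missingness indicator, True where a value is absent."""
        return self.frame.isna().to_numpy()

    @property
    def n_patients(self) -> int:
        return len(self.frame)

    def copy(self) -> "CohortTable":
        return CohortTable(self.frame.copy(), self.label.copy(),
                           None if self.outcome is None else self.outcome.copy())

    def select(self, columns: Sequence[str]) -> "CohortTable":
        return CohortTable(self.frame[list(columns)].copy(), self.label.copy(),
                           None if self.outcome is None else self.outcome.copy())

    # ---- CSV round trip (empty cell = missing; label column `diagnosis`) ----

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out[LABEL_COLUMN] = [LABEL_NAMES[v] for v in self.label]
        if self.outcome is not None:
            for c in self.outcome.columns:
                out[c] = self.outcome[c].to_numpy()
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, outcome_columns: Sequence[str] = ("died",)) -> "CohortTable":
        raw = pd.read_csv(path)
        if LABEL_COLUMN not in raw.columns:
            raise ValueError(f"cohort CSV lacks the {LABEL_COLUMN!r} column")
        label = raw[LABEL_COLUMN].map({"SLE": 0, "MAS": 1})
        if label.isna().any():
            raise ValueError("diagnosis column must contain only 'SLE'/'MAS'")
        present = [c for c in outcome_columns if c in raw.columns]
        outcome = raw[present].copy() if present else None
        frame = raw.drop(columns=[LABEL_COLUMN, *present]).astype(float)
        return cls(frame, label.to_numpy(int), outcome)


def spec_sidecar(config: CohortConfig) -> str:
    """JSON description of the generating configuration (written beside CSVs)."""
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        raise TypeError(type(obj))
    return json.dumps({
        "n_neg": config.n_neg, "n_pos": config.n_pos, "seed": config.seed,
        "n_noise": config.n_noise, "mas_mortality": list(config.mas_mortality),
        "features": [dataclasses.asdict(s) for s in config.features],
    }, indent=2, default=enc)


def _sample_cohort(config: CohortConfig, rng: np.random.Generator,
                   location_shift: float | Mapping[str, float] = 0.0,
                   scale: float = 1.0) -> CohortTable:
    n = config.n_neg + config.n_pos
    label = np.concatenate([np.zeros(config.n_neg, int), np.ones(config.n_pos, int)])
    cols: dict[str, np.ndarray] = {}
    for spec in config.features:
        neg = spec.dist_neg.sample(rng, config.n_neg)
        pos = spec.dist_pos.sample(rng, config.n_pos)
        x = np.concatenate([neg, pos])
        if spec.kind == "continuous" and (scale != 1.0 or location_shift):
            mu = np.concatenate([np.full(config.n_neg, spec.dist_neg.mean()),
                                 np.full(config.n_pos, spec.dist_pos.mean())])
            x = mu + scale * (x - mu)
            off = (location_shift.get(spec.name, 0.0)
                   if isinstance(location_shift, Mapping) else location_shift)
            if off:
                # offset expressed in overall (class-mixture) SD units
                sd = float(np.std(np.concatenate([
                    spec.dist_neg.sample(rng, 500), spec.dist_pos.sample(rng, 500)])))
                x = x + off * sd
        if spec.missing_rate > 0:
            x = x.copy()
            x[rng.random(n) < spec.missing_rate] = np.nan
        cols[spec.name] = x
    for i in range(config.n_noise):
        cols[f"noise_{i + 1:02d}"] = rng.normal(0.0, 1.0, size=n)
    # mortality: exactly round(rate * n_pos) deaths, all in the MAS group
    deaths_target = round(config.mas_mortality[0] / config.mas_mortality[1] * config.n_pos)
    died = np.zeros(n, int)
    dead_idx = rng.choice(config.n_pos, size=min(deaths_target, config.n_pos), replace=False)
    died[config.n_neg + dead_idx] = 1
    return CohortTable(pd.DataFrame(cols), label, pd.DataFrame({"died": died}))


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Draw one cohort; fully determined by ``config`` (including its seed)."""
    rng = np.random.default_rng(config.seed)
    return _sample_cohort(config, rng)


def generate_external_cohort(config: CohortConfig,
                             location_shift: float | Mapping[str, float] = 0.25,
                             scale: float = 1.1) -> CohortTable:
    """Cohort with mild inter-hospital drift.

    ``location_shift`` offsets every continuous feature by that many pooled
    class-SDs (or per-feature offsets via a mapping); ``scale`` inflates
    spread around the class means. ``location_shift=0, scale=1`` reproduces
    ``generate_cohort`` exactly under the same seed policy.
    """
    for v in ([location_shift] if not isinstance(location_shift, Mapping)
              else location_shift.values()):
        if not np.isfinite(v):
            raise ConfigError("location_shift: must be finite")
    if not np.isfinite(scale) or scale <= 0:
        raise ConfigError(f"scale: must be finite and positive, got {scale}")
    rng = np.random.default_rng(config.seed)
    return _sample_cohort(config, rng, location_shift=location_shift, scale=scale)
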