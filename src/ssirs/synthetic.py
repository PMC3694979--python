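"""Synthetic surgical-cohort generator with a known ground-truth risk model.

Cohorts mimic the structure of a large prospective surgical registry: one row
per operation with demographics, comorbidity flags, surgical factors, a
5-character procedure code whose 3-digit prefix defines a procedure group,
and a binary 30-day infection outcome. Outcomes are Bernoulli draws from a
configurable inverse-logit risk model with per-procedure-group log-odds
offsets, so every downstream stage (model derivation, group-score
construction, point scoring, evaluation) can be tested by parameter and
score recovery.

The default marginal distributions are plausibility choices (the emulated
registry is described only qualitatively in public sources); they live in
:func:`default_config`, not in code paths.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from ._errors import ValidationError
from .fracpoly import FPTransform, fp_apply

# Declared domains for the standard record schema.
SETTINGS = ("ambulatory", "inpatient_elective", "emergency")
WOUND_CLASSES = ("clean", "clean_contaminated", "contaminated", "dirty")
ANAESTHESIA = ("general", "other")
FUNCTIONAL_STATUS = ("independent", "partially_dependent", "dependent")
SEXES = ("female", "male")
ASA_CLASSES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class SurgicalRecord:
    """One operation: covariates, procedure code, and 30-day SSI outcome."""

    record_id: str
    age: float
    sex: str
    bmi: float
    smoker: bool
    functional_status: str
    peripheral_vascular_disease: bool
    metastatic_cancer: bool
    chronic_steroid_use: bool
    preop_sepsis: bool
    setting: str
    wound_class: str
    asa_class: int
    anaesthesia: str
    multiple_procedures: bool
    housestaff: bool
    duration_hours: float
    cpt_code: str
    ssi30: bool

    def __post_init__(self):
        if not self.bmi > 0:
            raise ValidationError("bmi must be positive", field="bmi")
        if self.duration_hours < 0:
            raise ValidationError("duration_hours must be nonnegative",
                                  field="duration_hours")
        if self.asa_class not in ASA_CLASSES:
            raise ValidationError(f"asa_class {self.asa_class} not in 1..5",
                                  field="asa_class")
        validate_cpt_code(self.cpt_code)
        for fname, domain in (("sex", SEXES), ("functional_status", FUNCTIONAL_STATUS),
                              ("setting", SETTINGS), ("wound_class", WOUND_CLASSES),
                              ("anaesthesia", ANAESTHESIA)):
            if getattr(self, fname) not in domain:
                raise ValidationError(
                    f"{fname}={getattr(self, fname)!r} not in {domain}", field=fname)


def validate_cpt_code(code: str) -> str:
    """Require a 5-character code whose first 3 characters are digits."""
    if not isinstance(code, str) or len(code) != 5 or not code[:3].isdigit():
        raise ValidationError(f"malformed CPT code {code!r}", field="cpt_code")
    return code


@dataclass(frozen=True)
class CovariateDef:
    """Definition of one covariate's marginal distribution."""

    name: str
    kind: str  # "binary" | "categorical" | "continuous"
    prevalence: float | None = None
    levels: tuple | None = None
    probs: tuple[float, ...] | None = None
    dist: str | None = None  # "normal_trunc" | "lognormal"
    params: dict = field(default_factory=dict)

    def validate(self):
        if self.kind == "binary":
            if self.prevalence is None or not 0 <= self.prevalence <= 1:
                raise ValidationError(
                    f"covariate {self.name!r}: prevalence must be in [0,1]",
                    field=self.name)
        elif self.kind == "categorical":
            if not self.levels or not self.probs or len(self.levels) != len(self.probs):
                raise ValidationError(
                    f"covariate {self.name!r}: levels and probs must align",
                    field=self.name)
            probs = np.asarray(self.probs, dtype=float)
            if np.any(probs < 0) or np.any(probs > 1) or abs(probs.sum() - 1) > 1e-9:
                raise ValidationError(
                    f"covariate {self.name!r}: level probabilities must be in "
                    "[0,1] and sum to 1", field=self.name)
        elif self.kind == "continuous":
            if self.dist not in ("normal_trunc", "lognormal"):
                raise ValidationError(
                    f"covariate {self.name!r}: unknown distribution {self.dist!r}",
                    field=self.name)
        else:
            raise ValidationError(
                f"covariate {self.name!r}: unknown kind {self.kind!r}",
                field=self.name)


@dataclass(frozen=True)
class TrueEffect:
    """Ground-truth log-odds contribution of one covariate.

    Continuous effects act on a fractional-polynomial basis of the raw value
    (``powers``/``shift``/``scale``), with one coefficient per basis column,
    so nonlinear ground truths are expressible.
    """

    covariate: str
    coef: float | tuple[float, ...] | None = None
    level_coefs: dict | None = None
    powers: tuple[float, ...] = (1.0,)
    shift: float = 0.0
    scale: float = 1.0

    def contribution(self, values: pd.Series) -> np.ndarray:
        if self.level_coefs is not None:
            return values.map(lambda v: self.level_coefs.get(v, 0.0)).to_numpy(float)
        coefs = np.atleast_1d(np.asarray(self.coef, dtype=float))
        x = values.to_numpy(float)
        if tuple(self.powers) == (1.0,):
            # identity: no positivity requirement (covers binary indicators)
            return coefs[0] * (x + self.shift) / self.scale
        t = FPTransform(self.covariate, tuple(self.powers), self.shift, self.scale)
        return fp_apply(x, t) @ coefs


@dataclass(frozen=True)
class TrueModel:
    intercept: float | None
    effects: tuple[TrueEffect, ...]


@dataclass(frozen=True)
class CptGroupConfig:
    """Procedure-group structure: count, log-odds offsets, sampling weights.

    Offsets (between-group risk heterogeneity) and weights default to seeded
    draws — normal offsets, lognormal weights — reproducible from the cohort
    seed alone.
    """

    n_groups: int = 290
    offset_sd: float = 0.6
    offsets: tuple[float, ...] | None = None
    weights: tuple[float, ...] | None = None
    weight_sd: float = 1.2

    def validate(self):
        if self.n_groups < 1:
            raise ValidationError("cpt_groups: n_groups must be >= 1",
                                  field="cpt_groups.n_groups")
        if self.n_groups > 900:
            raise ValidationError("cpt_groups: at most 900 3-digit prefixes",
                                  field="cpt_groups.n_groups")
        for attr in ("offsets", "weights"):
            vals = getattr(self, attr)
            if vals is not None and len(vals) != self.n_groups:
                raise ValidationError(
                    f"cpt_groups.{attr} length must equal n_groups", field=attr)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or w.sum() <= 0:
                raise ValidationError(
                    "cpt_groups.weights must be nonnegative, not all zero",
                    field="cpt_groups.weights")


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort (seeded, bit-reproducible)."""

    n_records: int
    seed: int
    covariate_spec: tuple[CovariateDef, ...]
    true_model: TrueModel
    cpt_groups: CptGroupConfig = field(default_factory=CptGroupConfig)
    event_rate_target: float | None = None

    def validate(self):
        if self.n_records < 0:
            raise ValidationError("n_records must be nonnegative", field="n_records")
        for cov in self.covariate_spec:
            cov.validate()
        self.cpt_groups.validate()
        if self.event_rate_target is not None and not 0 < self.event_rate_target < 1:
            raise ValidationError("event_rate_target must be in (0,1)",
                                  field="event_rate_target")
        names = {c.name for c in self.covariate_spec}
        for eff in self.true_model.effects:
            if eff.covariate not in names:
                raise ValidationError(
                    f"true_model references unknown covariate {eff.covariate!r}",
                    field=eff.covariate)


def group_prefixes(config: CohortConfig) -> list[str]:
    """The 3-digit prefixes of the configured procedure groups."""
    return [f"{100 + i:03d}" for i in range(config.cpt_groups.n_groups)]


def group_offsets(config: CohortConfig) -> np.ndarray:
    """Per-group log-odds offsets, drawn once per group (seeded)."""
    g = config.cpt_groups
    if g.offsets is not None:
        return np.asarray(g.offsets, dtype=float)
    rng = np.random.default_rng([config.seed, 1])
    return rng.normal(0.0, g.offset_sd, g.n_groups)


def group_weights(config: CohortConfig) -> np.ndarray:
    g = config.cpt_groups
    if g.weights is not None:
        w = np.asarray(g.weights, dtype=float)
    else:
        rng = np.random.default_rng([config.seed, 2])
        w = rng.lognormal(0.0, g.weight_sd, g.n_groups)
    return w / w.sum()


def _draw_covariates(config: CohortConfig) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, 3])
    n = config.n_records
    data: dict[str, np.ndarray | pd.Series] = {}
    data["record_id"] = np.array([f"r{i:07d}" for i in range(n)])
    for cov in config.covariate_spec:
        if cov.kind == "binary":
            data[cov.name] = rng.random(n) < cov.prevalence
        elif cov.kind == "categorical":
            idx = rng.choice(len(cov.levels), size=n, p=np.asarray(cov.probs))
            data[cov.name] = pd.Series(idx).map(dict(enumerate(cov.levels)))
        else:
            p = cov.params
            if cov.dist == "normal_trunc":
                lo = p.get("floor", -np.inf)
                a = (lo - p["mean"]) / p["sd"] if np.isfinite(lo) else -np.inf
                data[cov.name] = truncnorm.rvs(
                    a, np.inf, loc=p["mean"], scale=p["sd"], size=n, random_state=rng)
            else:  # lognormal
                data[cov.name] = rng.lognormal(p["meanlog"], p["sdlog"], n)
    df = pd.DataFrame(data)

    gidx = rng.choice(config.cpt_groups.n_groups, size=n, p=group_weights(config))
    prefixes = np.array(group_prefixes(config))
    suffix = rng.integers(0, 100, n)
    df["cpt_code"] = [f"{prefixes[g]}{s:02d}" for g, s in zip(gidx, suffix)]
    df["_group_index"] = gidx
    return df


def _linear_predictor_no_intercept(df: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    lp = np.zeros(len(df))
    for eff in config.true_model.effects:
        if eff.covariate not in df.columns:
            raise ValidationError(
                f"covariate {eff.covariate!r} in true_model absent from record",
                field=eff.covariate)
        lp += eff.contribution(df[eff.covariate])
    offsets = group_offsets(config)
    lp += offsets[df["_group_index"].to_numpy()]
    return lp


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    def mean_risk(c: float) -> float:
        return float(np.mean(expit(c + lp))) - target

    return float(brentq(mean_risk, -40.0, 10.0, xtol=1e-12))


def calibrate_config(config: CohortConfig) -> CohortConfig:
    """Return the config with its intercept solved for the event-rate target.

    Uses the cohort's own (seeded) covariate draw, so a subsequent
    :func:`generate_cohort` call sees exactly this intercept.
    """
    config.validate()
    if config.event_rate_target is None:
        raise ValidationError("event_rate_target not set", field="event_rate_target")
    if config.n_records == 0:
        raise ValidationError("cannot calibrate on an empty cohort", field="n_records")
    df = _draw_covariates(config)
    lp = _linear_predictor_no_intercept(df, config)
    intercept = _solve_intercept(lp, config.event_rate_target)
    return dataclasses.replace(
        config, true_model=dataclasses.replace(config.true_model, intercept=intercept))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a cohort as a DataFrame, one row per operation.

    Outcomes are Bernoulli draws from the ground-truth inverse-logit risk.
    If the true-model intercept is unset, it is solved so the mean risk hits
    ``event_rate_target`` (identical to :func:`calibrate_config`).
    """
    config.validate()
    if config.n_records == 0:
        cols = (["record_id"] + [c.name for c in config.covariate_spec]
                + ["cpt_code", "ssi30"])
        return pd.DataFrame(columns=cols)
    df = _draw_covariates(config)
    lp = _linear_predictor_no_intercept(df, config)
    intercept = config.true_model.intercept
    if intercept is None:
        if config.event_rate_target is None:
            raise ValidationError(
                "either true_model.intercept or event_rate_target must be set",
                field="true_model.intercept")
        intercept = _solve_intercept(lp, config.event_rate_target)
    p = expit(intercept + lp)
    rng = np.random.default_rng([config.seed, 4])
    df["ssi30"] = rng.random(len(df)) < p
    return df.drop(columns=["_group_index"])


def true_risk(record, config: CohortConfig) -> float:
    """Ground-truth SSI probability for one record under the config's model.

    ``record`` may be a :class:`SurgicalRecord`, a mapping, or a Series. The
    config's intercept must be set (see :func:`calibrate_config`).
    """
    config.validate()
    if config.true_model.intercept is None:
        raise ValidationError(
            "true_model.intercept is unset; call calibrate_config first",
            field="true_model.intercept")
    if isinstance(record, SurgicalRecord):
        record = dataclasses.asdict(record)
    elif isinstance(record, pd.Series):
        record = record.to_dict()
    df = pd.DataFrame([record])
    prefix = validate_cpt_code(record["cpt_code"])[:3]
    prefixes = group_prefixes(config)
    try:
        df["_group_index"] = prefixes.index(prefix)
    except ValueError:
        raise ValidationError(f"CPT prefix {prefix!r} not in configured groups",
                              field="cpt_code")
    lp = _linear_predictor_no_intercept(df, config)
    return float(expit(config.true_model.intercept + lp[0]))


def default_covariates() -> tuple[CovariateDef, ...]:
    """Default marginals, mirroring the emulated registry qualitatively:
    ~1/3 ambulatory, ~1/2 elective inpatient, ~10% emergency; >50% clean
    wounds; >50% ASA 1-2; >90% general anaesthesia; mean duration 1.8 h."""
    return (
        CovariateDef("age", "continuous", dist="normal_trunc",
                     params={"mean": 55.0, "sd": 16.0, "floor": 18.0}),
        CovariateDef("sex", "categorical", levels=SEXES, probs=(0.55, 0.45)),
        CovariateDef("bmi", "continuous", dist="normal_trunc",
                     params={"mean": 28.5, "sd": 6.5, "floor": 14.0}),
        CovariateDef("smoker", "binary", prevalence=0.20),
        CovariateDef("functional_status", "categorical",
                     levels=FUNCTIONAL_STATUS, probs=(0.92, 0.06, 0.02)),
        CovariateDef("peripheral_vascular_disease", "binary", prevalence=0.025),
        CovariateDef("metastatic_cancer", "binary", prevalence=0.02),
        CovariateDef("chronic_steroid_use", "binary", prevalence=0.03),
        CovariateDef("preop_sepsis", "binary", prevalence=0.03),
        CovariateDef("setting", "categorical", levels=SETTINGS,
                     probs=(0.35, 0.55, 0.10)),
        CovariateDef("wound_class", "categorical", levels=WOUND_CLASSES,
                     probs=(0.55, 0.30, 0.08, 0.07)),
        CovariateDef("asa_class", "categorical", levels=ASA_CLASSES,
                     probs=(0.15, 0.45, 0.30, 0.09, 0.01)),
        CovariateDef("anaesthesia", "categorical", levels=ANAESTHESIA,
                     probs=(0.92, 0.08)),
        CovariateDef("multiple_procedures", "binary", prevalence=0.35),
        CovariateDef("housestaff", "binary", prevalence=0.55),
        # lognormal(meanlog, sdlog) with mean exp(m + s^2/2) = 1.8 h
        CovariateDef("duration_hours", "continuous", dist="lognormal",
                     params={"meanlog": 0.343, "sdlog": 0.70}),
    )


def default_true_effects() -> tuple[TrueEffect, ...]:
    """Ground-truth effects: nonlinear BMI (quadratic on bmi/10) and log
    duration, plus binary/categorical effects of plausible magnitude."""
    return (
        TrueEffect("age", coef=0.008),
        TrueEffect("bmi", coef=(0.09,), powers=(2.0,), scale=10.0),
        TrueEffect("smoker", coef=0.30),
        TrueEffect("functional_status",
                   level_coefs={"partially_dependent": 0.30, "dependent": 0.45}),
        TrueEffect("peripheral_vascular_disease", coef=0.40),
        TrueEffect("metastatic_cancer", coef=0.55),
        TrueEffect("chronic_steroid_use", coef=0.40),
        TrueEffect("preop_sepsis", coef=0.70),
        TrueEffect("setting",
                   level_coefs={"inpatient_elective": 0.55, "emergency": 0.95}),
        TrueEffect("wound_class",
                   level_coefs={"clean_contaminated": 0.35, "contaminated": 0.75,
                                "dirty": 1.05}),
        TrueEffect("asa_class", level_coefs={2: 0.15, 3: 0.45, 4: 0.75, 5: 1.0}),
        TrueEffect("anaesthesia", level_coefs={"other": -0.40}),
        TrueEffect("multiple_procedures", coef=0.30),
        TrueEffect("duration_hours", coef=(0.55,), powers=(0.0,), shift=0.05),
    )


def default_config(n_records: int = 20_000, seed: int = 0,
                   event_rate_target: float = 0.039,
                   n_groups: int = 290, offset_sd: float = 0.6) -> CohortConfig:
    """A ready-to-use NSQIP-scale-like configuration (scaled down by default)."""
    return CohortConfig(
        n_records=n_records,
        seed=seed,
        covariate_spec=default_covariates(),
        true_model=TrueModel(intercept=None, effects=default_true_effects()),
        cpt_groups=CptGroupConfig(n_groups=n_groups, offset_sd=offset_sd),
        event_rate_target=event_rate_target,
    )


def records_from_frame(df: pd.DataFrame) -> list[SurgicalRecord]:
    """Materialize validated record objects from a standard-schema frame."""
    return [SurgicalRecord(**row) for row in df.to_dict(orient="records")]
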