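"""Cohort CSV schema and pipeline configuration files."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._errors import ValidationError
from .synthetic import (ANAESTHESIA, ASA_CLASSES, FUNCTIONAL_STATUS, SETTINGS,
                        SEXES, WOUND_CLASSES)

logger = logging.getLogger(__name__)

BOOL_COLUMNS = ("smoker", "peripheral_vascular_disease", "metastatic_cancer",
                "chronic_steroid_use", "preop_sepsis", "multiple_procedures",
                "housestaff", "ssi30")
FLOAT_COLUMNS = ("age", "bmi", "duration_hours")
CATEGORY_DOMAINS = {
    "sex": SEXES,
    "functional_status": FUNCTIONAL_STATUS,
    "setting": SETTINGS,
    "wound_class": WOUND_CLASSES,
    "anaesthesia": ANAESTHESIA,
}

# fixed, documented header order
COHORT_COLUMNS = (
    "record_id", "age", "sex", "bmi", "smoker", "functional_status",
    "peripheral_vascular_disease", "metastatic_cancer", "chronic_steroid_use",
    "preop_sepsis", "setting", "wound_class", "asa_class", "anaesthesia",
    "multiple_procedures", "housestaff", "duration_hours", "cpt_code", "ssi30",
)

_TRUTHY = {"true", "1", "yes"}
_FALSY = {"false", "0", "no"}


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a cohort CSV with the canonical column order."""
    missing = [c for c in COHORT_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"cohort frame lacks columns {missing}",
                              field=missing[0])
    records.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


def _parse_bool(val, col: str, row: int) -> bool:
    s = str(val).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"row {row}: column {col!r} has non-boolean value "
                          f"{val!r}", field=col)


def read_cohort(path, missing_covariate_threshold: float = 0.01) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Covariate columns missing in at least ``missing_covariate_threshold`` of
    rows are dropped entirely (screening rule); remaining rows with any
    missing value are dropped complete-case, with the count logged. Unknown
    columns or out-of-domain values raise, naming the column and data row.
    """
    df = pd.read_csv(path, dtype={"record_id": str, "cpt_code": str})
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown column(s) {unknown} in cohort file",
                              field=unknown[0])
    required = ("record_id", "cpt_code", "ssi30")
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}", field=col)

    # covariate-level screening: drop columns with too much missingness
    covariate_cols = [c for c in df.columns if c not in required]
    dropped_covariates = []
    for col in covariate_cols:
        frac = df[col].isna().mean()
        if frac >= missing_covariate_threshold and frac > 0:
            dropped_covariates.append(col)
    if dropped_covariates:
        logger.warning("dropping covariates with >= %.0f%% missing: %s",
                       100 * missing_covariate_threshold, dropped_covariates)
        df = df.drop(columns=dropped_covariates)

    # complete-case on the rest
    incomplete = df.isna().any(axis=1)
    n_dropped = int(incomplete.sum())
    if n_dropped:
        logger.warning("dropping %d incomplete row(s) of %d", n_dropped, len(df))
        df = df[~incomplete].reset_index(drop=True)

    for col in BOOL_COLUMNS:
        if col in df.columns:
            df[col] = [
                _parse_bool(v, col, i + 2) for i, v in zip(df.index, df[col])]
    for col in FLOAT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[df[col].isna()]
            if len(bad):
                raise ValidationError(
                    f"row {bad[0] + 2}: column {col!r} is not numeric", field=col)
    for col, domain in CATEGORY_DOMAINS.items():
        if col in df.columns:
            bad = df.index[~df[col].isin(domain)]
            if len(bad):
                raise ValidationError(
                    f"row {bad[0] + 2}: column {col!r} has value "
                    f"{df[col].iloc[bad[0]]!r} outside {domain}", field=col)
    if "asa_class" in df.columns:
        asa = pd.to_numeric(df["asa_class"], errors="coerce")
        bad = df.index[~asa.isin(ASA_CLASSES)]
        if len(bad):
            raise ValidationError(
                f"row {bad[0] + 2}: asa_class {df['asa_class'].iloc[bad[0]]!r} "
                "not in 1..5", field="asa_class")
        df["asa_class"] = asa.astype(int)
    bad = df.index[~df["cpt_code"].str.fullmatch(r"\d{3}\w{2}", na=False)]
    if len(bad):
        raise ValidationError(
            f"row {bad[0] + 2}: malformed cpt_code "
            f"{df['cpt_code'].iloc[bad[0]]!r}", field="cpt_code")
    return df


@dataclass
class SimulateBlock:
    """Cohort-generation parameters (applied to the default ground truth)."""

    n_records: int = 20_000
    event_rate_target: float = 0.039
    n_groups: int = 290
    offset_sd: float = 0.6


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, serializable as YAML."""

    outdir: str
    seed: int = 0
    cohort_csv: str | None = None
    simulate: SimulateBlock | None = None
    stage1_p_entry: float = 0.05
    stage2_p_entry: float = 1e-4
    fp_max_degree: int = 2
    interactions: list = field(default_factory=list)  # list of [a, b] pairs
    categorization: str | dict = "quintiles"
    reference_covariate: str = "bmi"
    reference_delta: float = 5.0
    hl_groups: int = 10
    ci_level: float = 0.95

    def validate(self):
        for name in ("stage1_p_entry", "stage2_p_entry"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0,1)", field=name)
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0,1)", field="ci_level")
        if (self.cohort_csv is None) == (self.simulate is None):
            raise ValidationError(
                "exactly one of cohort_csv / simulate must be given",
                field="cohort_csv")
        if isinstance(self.categorization, str):
            from .scoring import PRESET_BOUNDARIES
            if self.categorization not in ("quintiles",) and \
                    self.categorization not in PRESET_BOUNDARIES:
                raise ValidationError(
                    f"unknown categorization preset {self.categorization!r}",
                    field="categorization")

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir,
            "seed": self.seed,
            "cohort_csv": self.cohort_csv,
            "stage1_p_entry": self.stage1_p_entry,
            "stage2_p_entry": self.stage2_p_entry,
            "fp_max_degree": self.fp_max_degree,
            "interactions": [list(p) for p in self.interactions],
            "categorization": self.categorization,
            "reference_covariate": self.reference_covariate,
            "reference_delta": self.reference_delta,
            "hl_groups": self.hl_groups,
            "ci_level": self.ci_level,
        }
        if self.simulate is not None:
            d["simulate"] = vars(self.simulate).copy()
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        cfg = cls(simulate=None if sim is None else SimulateBlock(**sim), **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
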