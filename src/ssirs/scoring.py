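"""Conversion of a fitted logistic model into an integer point score.

The Sullivan point-system construction: pick a reference risk increment (by
default the log-odds change induced by a 5-unit BMI increase) as the worth
of one point; for every covariate category, points are the category's
log-odds distance from its reference category divided by that unit, rounded
to the nearest integer (halves away from zero). A single-covariate logistic
fit then maps integer scores back to predicted risks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._errors import ValidationError
from ._util import as_binary, round_half_away
from .derivation import FittedRiskModel, fit_logistic
from .design import BinaryTerm, CategoricalTerm, ContinuousTerm

POINT_TABLE_FORMAT = "ssirs-point-table"

# Category boundaries quoted as the published score's influential ranges.
PRESET_BOUNDARIES: dict[str, dict[str, list[float]]] = {
    "published": {
        "bmi": [25.0, 30.0, 35.0],
        "duration_hours": [0.5, 1.0, 2.0, 3.5],
        "cpt3_score": [0.9, 1.262],
    },
}


@dataclass(frozen=True)
class ScoreRiskMap:
    """Logistic map from integer score to predicted event probability."""

    intercept: float
    beta: float
    converged: bool = True

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "beta": self.beta,
                "converged": self.converged}

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreRiskMap":
        return cls(intercept=d["intercept"], beta=d["beta"],
                   converged=d.get("converged", True))


@dataclass(frozen=True)
class CategoryPoints:
    """One scored category of one covariate."""

    label: str
    points: int
    is_reference: bool
    # continuous covariates: (lower, upper] interval, representative value
    lower: float | None = None
    upper: float | None = None
    representative: float | None = None
    # binary/categorical covariates: the matching level
    level: object | None = None

    def to_dict(self) -> dict:
        return {"label": self.label, "points": self.points,
                "is_reference": self.is_reference, "lower": self.lower,
                "upper": self.upper, "representative": self.representative,
                "level": self.level}


@dataclass(frozen=True)
class CovariateEntry:
    covariate: str
    kind: str
    categories: tuple[CategoryPoints, ...]

    def category_for(self, value) -> CategoryPoints:
        if self.kind == "continuous":
            x = float(value)
            for cat in self.categories:
                lo = -math.inf if cat.lower is None else cat.lower
                hi = math.inf if cat.upper is None else cat.upper
                if lo < x <= hi or (x == lo == -math.inf):
                    return cat
            raise ValidationError(
                f"value {value!r} falls in no category of {self.covariate!r}",
                field=self.covariate)
        for cat in self.categories:
            if cat.level == value:
                return cat
        raise ValidationError(
            f"level {value!r} not in point table for {self.covariate!r}",
            field=self.covariate)

    @property
    def min_points(self) -> int:
        return min(c.points for c in self.categories)

    @property
    def max_points(self) -> int:
        return max(c.points for c in self.categories)

    def to_dict(self) -> dict:
        return {"covariate": self.covariate, "kind": self.kind,
                "categories": [c.to_dict() for c in self.categories]}


@dataclass
class PointScoreTable:
    """Integer point table plus the score-to-risk logistic map."""

    reference_unit: float
    entries: tuple[CovariateEntry, ...]
    base_constant: int = 0
    risk_map: ScoreRiskMap | None = None

    def __post_init__(self):
        if self.reference_unit <= 0:
            raise ValidationError("reference_unit must be positive",
                                  field="reference_unit")
        for e in self.entries:
            if sum(1 for c in e.categories if c.is_reference) != 1:
                raise ValidationError(
                    f"covariate {e.covariate!r} must have exactly one "
                    "reference category", field=e.covariate)

    @property
    def score_range(self) -> tuple[int, int]:
        lo = self.base_constant + sum(e.min_points for e in self.entries)
        hi = self.base_constant + sum(e.max_points for e in self.entries)
        return lo, hi

    def entry_for(self, covariate: str) -> CovariateEntry:
        for e in self.entries:
            if e.covariate == covariate:
                return e
        raise KeyError(covariate)

    def to_dict(self) -> dict:
        return {"format": POINT_TABLE_FORMAT, "version": 1,
                "reference_unit": self.reference_unit,
                "base_constant": self.base_constant,
                "score_range": list(self.score_range),
                "risk_map": None if self.risk_map is None else self.risk_map.to_dict(),
                "entries": [e.to_dict() for e in self.entries]}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "PointScoreTable":
        if d.get("format") != POINT_TABLE_FORMAT:
            raise ValidationError("not a point-table JSON document", field="format")
        entries = tuple(
            CovariateEntry(
                covariate=e["covariate"], kind=e["kind"],
                categories=tuple(CategoryPoints(**c) for c in e["categories"]))
            for e in d["entries"])
        rm = d.get("risk_map")
        return cls(reference_unit=d["reference_unit"], entries=entries,
                   base_constant=d.get("base_constant", 0),
                   risk_map=None if rm is None else ScoreRiskMap.from_dict(rm))

    @classmethod
    def from_json(cls, path) -> "PointScoreTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def card_text(self) -> str:
        """Printable bedside card: category -> points."""
        lo, hi = self.score_range
        lines = [f"point score card (possible range {lo} to {hi})"]
        for e in self.entries:
            lines.append(f"{e.covariate}:")
            for c in e.categories:
                ref = "  (reference)" if c.is_reference else ""
                lines.append(f"    {c.label:<28s} {c.points:+d}{ref}")
        if self.risk_map is not None:
            lines.append(
                f"risk(score) = 1/(1+exp(-({self.risk_map.intercept:.4f} "
                f"+ {self.risk_map.beta:.4f} x score)))")
        return "\n".join(lines)


def _interval_label(name: str, lo: float | None, hi: float | None) -> str:
    if lo is None:
        return f"{name} <= {hi:g}"
    if hi is None:
        return f"{name} > {lo:g}"
    return f"{lo:g} < {name} <= {hi:g}"


def _continuous_entry(name: str, term: ContinuousTerm, coefs: np.ndarray,
                      boundaries: list[float], values: np.ndarray,
                      unit: float) -> CovariateEntry:
    """Categorize a continuous model covariate and assign points.

    Intervals are (b_k, b_{k+1}]; representatives are interval midpoints,
    except open-ended extremes, which use the observed in-category median
    (falling back to the boundary when a category is empty in the data).
    """
    bounds = sorted(boundaries)
    edges = [None] + bounds + [None]
    cats: list[tuple[float | None, float | None, float]] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo is not None and hi is not None:
            rep = 0.5 * (lo + hi)
        else:
            mask = np.ones(len(values), dtype=bool)
            if lo is not None:
                mask &= values > lo
            if hi is not None:
                mask &= values <= hi
            if mask.any():
                rep = float(np.median(values[mask]))
            else:
                rep = float(lo if lo is not None else hi)
        cats.append((lo, hi, rep))

    # reference category: the one containing the observed median
    med = float(np.median(values))
    ref_idx = next(
        i for i, (lo, hi, _) in enumerate(cats)
        if (lo is None or med > lo) and (hi is None or med <= hi))
    ref_rep = cats[ref_idx][2]
    ref_contrib = term.contribution(ref_rep, coefs)

    out = []
    for i, (lo, hi, rep) in enumerate(cats):
        delta = term.contribution(rep, coefs) - ref_contrib
        pts = 0 if i == ref_idx else round_half_away(delta / unit)
        out.append(CategoryPoints(
            label=_interval_label(name, lo, hi), points=pts,
            is_reference=(i == ref_idx), lower=lo, upper=hi,
            representative=rep))
    return CovariateEntry(covariate=name, kind="continuous",
                          categories=tuple(out))


def build_point_table(model: FittedRiskModel, data: pd.DataFrame,
                      categorization: dict[str, list[float]],
                      reference_covariate: str = "bmi",
                      reference_delta: float = 5.0,
                      base_constant: int = 0) -> PointScoreTable:
    """Convert a fitted model into an integer point table.

    One point is worth ``B``, the absolute log-odds change produced by
    raising ``reference_covariate`` by ``reference_delta`` from its observed
    median (through the covariate's modeled transform). Category points are
    ``round(beta_i * (W_ij - W_iREF) / B)``. Interaction terms carry no
    points (the table scores main effects only; documented simplification).
    """
    if reference_delta <= 0:
        raise ValidationError("reference_delta must be positive",
                              field="reference_delta")
    try:
        ref_ft = model.term_for(reference_covariate)
    except KeyError:
        raise ValidationError(
            f"reference covariate {reference_covariate!r} not in model",
            field="reference_covariate")
    if not isinstance(ref_ft.term, ContinuousTerm):
        raise ValidationError("reference covariate must be continuous",
                              field="reference_covariate")
    for name in categorization:
        if name not in model.term_names:
            raise ValidationError(
                f"categorization covers unmodeled covariate {name!r}",
                field=name)

    ref_coefs = np.asarray(ref_ft.coefs)
    x0 = float(np.median(np.asarray(data[reference_covariate], dtype=float)))
    unit = abs(ref_ft.term.contribution(x0 + reference_delta, ref_coefs)
               - ref_ft.term.contribution(x0, ref_coefs))
    if unit == 0 or not np.isfinite(unit):
        raise ValidationError(
            "reference coefficient is zero: point unit undefined",
            field="reference_covariate")

    entries = []
    for ft in model.terms:
        term = ft.term
        coefs = np.asarray(ft.coefs)
        if isinstance(term, ContinuousTerm):
            if term.name not in categorization:
                raise ValidationError(
                    f"continuous covariate {term.name!r} needs category "
                    "boundaries", field=term.name)
            entries.append(_continuous_entry(
                term.name, term, coefs, categorization[term.name],
                np.asarray(data[term.name], dtype=float), unit))
        elif isinstance(term, BinaryTerm):
            entries.append(CovariateEntry(
                covariate=term.name, kind="binary",
                categories=(
                    CategoryPoints(label=f"{term.name} = no", points=0,
                                   is_reference=True, level=False),
                    CategoryPoints(label=f"{term.name} = yes",
                                   points=round_half_away(coefs[0] / unit),
                                   is_reference=False, level=True))))
        elif isinstance(term, CategoricalTerm):
            cats = [CategoryPoints(label=f"{term.name} = {term.reference}",
                                   points=0, is_reference=True,
                                   level=term.reference)]
            for lev, c in zip(term.levels[1:], coefs):
                cats.append(CategoryPoints(label=f"{term.name} = {lev}",
                                           points=round_half_away(c / unit),
                                           is_reference=False, level=lev))
            entries.append(CovariateEntry(covariate=term.name,
                                          kind="categorical",
                                          categories=tuple(cats)))
        # interaction terms: no points assigned
    return PointScoreTable(reference_unit=float(unit), entries=tuple(entries),
                           base_constant=base_constant)


def _record_value(record, name: str):
    if isinstance(record, pd.Series) or isinstance(record, dict):
        try:
            return record[name]
        except KeyError:
            raise ValidationError(f"record lacks covariate {name!r}", field=name)
    if hasattr(record, name):
        return getattr(record, name)
    raise ValidationError(f"record lacks covariate {name!r}", field=name)


def ssirs_score(record, cpt3: float, table: PointScoreTable) -> int:
    """Integer risk score for one record: sum of category points plus the
    table's base constant. ``cpt3`` supplies the record's procedure-group
    score (covariate name ``cpt3_score``)."""
    total = table.base_constant
    for entry in table.entries:
        if entry.covariate == "cpt3_score":
            value = cpt3
        else:
            value = _record_value(record, entry.covariate)
        total += entry.category_for(value).points
    lo, hi = table.score_range
    assert lo <= total <= hi
    return int(total)


def score_cohort(records: pd.DataFrame, cpt3_scores, table: PointScoreTable) -> np.ndarray:
    """Vectorized convenience wrapper over :func:`ssirs_score`."""
    cpt3_scores = np.asarray(cpt3_scores, dtype=float)
    return np.array([
        ssirs_score(row, cpt3_scores[i], table)
        for i, (_, row) in enumerate(records.iterrows())])


def fit_score_risk_map(scores, y) -> ScoreRiskMap:
    """Single-covariate logistic MLE of outcome on integer score."""
    scores = np.asarray(scores, dtype=float)
    y = as_binary(y)
    if np.all(scores == scores[0]):
        raise ValidationError("scores are constant; map is unidentifiable",
                              field="scores")
    model = fit_logistic(scores[:, None], y)
    return ScoreRiskMap(intercept=model.intercept,
                        beta=float(model.terms[0].coefs[0]),
                        converged=model.converged)


def risk_from_score(score, map: ScoreRiskMap):
    """Predicted probability ``1/(1 + exp(-(intercept + beta*score)))``."""
    return expit(map.intercept + map.beta * np.asarray(score, dtype=float))


def nnt(baseline_risk: float, relative_risk: float) -> float:
    """Number needed to treat: ``1 / (baseline_risk * (1 - relative_risk))``.

    ``relative_risk`` is the treated-to-baseline risk ratio; 1.0 (no effect)
    yields infinity. Harmful interventions (ratio > 1) raise instead of
    silently returning a negative number.
    """
    if not 0 < baseline_risk <= 1:
        raise ValidationError("baseline_risk must be in (0, 1]",
                              field="baseline_risk")
    if relative_risk < 0:
        raise ValidationError("relative_risk must be nonnegative",
                              field="relative_risk")
    if relative_risk > 1:
        raise ValidationError(
            "relative_risk > 1 indicates harm: NNT undefined (negative benefit)",
            field="relative_risk")
    arr = baseline_risk * (1.0 - relative_risk)
    if arr == 0:
        return math.inf
    return 1.0 / arr
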