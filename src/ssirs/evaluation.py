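"""Model performance: discrimination, calibration, and the legacy 0-3
surveillance index used as a comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import chi2, norm

from ._errors import ValidationError
from ._util import as_binary
from .reporting import percent
from .scoring import ScoreRiskMap, risk_from_score
from .synthetic import validate_cpt_code

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscriminationReport:
    c_statistic: float
    ci_low: float
    ci_high: float
    n_pairs: int
    method: str = "delong"

    def __post_init__(self):
        if not (0.0 <= self.c_statistic <= 1.0):
            raise ValidationError("c-statistic outside [0,1]", field="c_statistic")
        if not (self.ci_low <= self.c_statistic <= self.ci_high):
            raise ValidationError("CI does not bracket the c-statistic",
                                  field="ci_low")

    def to_dict(self) -> dict:
        return {"c_statistic": self.c_statistic, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n_pairs": self.n_pairs,
                "method": self.method}


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n - 1 and xs[j + 1] == xs[i]:
            j += 1
        ranks[i:j + 1] = 0.5 * (i + j) + 1.0
        i = j + 1
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def c_statistic(predictions, y, level: float = 0.95) -> DiscriminationReport:
    """Concordance probability with an asymptotic (DeLong placement
    components) confidence interval.

    c = (concordant + 0.5*tied) / (event, non-event) pairs, computed via
    midranks; equals the brute-force pair count exactly.
    """
    p = np.asarray(predictions, dtype=float)
    y = as_binary(y)
    m = int(y.sum())
    n_neg = len(y) - m
    if m == 0 or n_neg == 0:
        raise ValidationError("both outcome classes required", field="y")
    pos, neg = p[y == 1], p[y == 0]
    tz = _midranks(np.concatenate([pos, neg]))
    tx = _midranks(pos)
    ty = _midranks(neg)
    v10 = (tz[:m] - tx) / n_neg           # placements of events
    v01 = 1.0 - (tz[m:] - ty) / m         # placements of non-events
    auc = float(v10.mean())
    var = 0.0
    if m > 1:
        var += float(np.var(v10, ddof=1)) / m
    if n_neg > 1:
        var += float(np.var(v01, ddof=1)) / n_neg
    z = norm.ppf(0.5 + level / 2)
    se = np.sqrt(var)
    return DiscriminationReport(
        c_statistic=auc,
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
        n_pairs=m * n_neg,
        method="delong")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HLResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame = field(compare=False)

    def __iter__(self):
        return iter((self.statistic, self.df, self.p_value))


def hosmer_lemeshow(predictions, y, groups: int = 10) -> HLResult:
    """Hosmer-Lemeshow goodness-of-fit over groups of predicted risk.

    Records are grouped by quantiles of the predicted probability (ties stay
    together, so fewer groups may result); groups whose expected event or
    non-event count is zero are merged into their neighbor (logged). The
    statistic sums (O-E)^2 / (E(1-E/n)) over final groups; df = groups - 2.
    """
    p = np.asarray(predictions, dtype=float)
    y = as_binary(y)
    if groups < 2:
        raise ValidationError("groups must be >= 2", field="groups")
    if len(p) < groups:
        raise ValidationError("fewer records than groups", field="groups")
    if len(np.unique(p)) < 2:
        bins = pd.Series(np.zeros(len(p), dtype=int))
    else:
        bins = pd.qcut(p, groups, duplicates="drop")
    agg = (pd.DataFrame({"p": p, "y": y, "bin": bins})
           .groupby("bin", observed=True)
           .agg(n=("y", "size"), observed=("y", "sum"), expected=("p", "sum")))
    rows = agg.reset_index(drop=True)

    merged = []
    for _, row in rows.iterrows():
        if merged and (merged[-1]["expected"] <= 0
                       or merged[-1]["n"] - merged[-1]["expected"] <= 0):
            logger.info("HL: merging degenerate group into neighbor")
            merged[-1] = {k: merged[-1][k] + row[k]
                          for k in ("n", "observed", "expected")}
        else:
            merged.append(dict(row))
    # a trailing degenerate group merges backwards
    while len(merged) > 1 and (merged[-1]["expected"] <= 0
                               or merged[-1]["n"] - merged[-1]["expected"] <= 0):
        logger.info("HL: merging trailing degenerate group")
        last = merged.pop()
        merged[-1] = {k: merged[-1][k] + last[k]
                      for k in ("n", "observed", "expected")}

    table = pd.DataFrame(merged)
    g = len(table)
    pbar = table["expected"] / table["n"]
    stat = float((((table["observed"] - table["expected"]) ** 2)
                  / (table["n"] * pbar * (1 - pbar))).sum())
    df = g - 2
    p_value = float(chi2.sf(stat, df)) if df >= 1 else float("nan")
    return HLResult(statistic=stat, df=df, p_value=p_value, table=table)


def exact_binomial_ci(events: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact interval via beta-distribution quantiles."""
    if n < 1 or not 0 <= events <= n:
        raise ValidationError(f"invalid counts events={events}, n={n}", field="events")
    alpha = 1.0 - level
    low = 0.0 if events == 0 else float(beta_dist.ppf(alpha / 2, events,
                                                      n - events + 1))
    high = 1.0 if events == n else float(beta_dist.ppf(1 - alpha / 2, events + 1,
                                                       n - events))
    return low, high


@dataclass(frozen=True)
class ScoreLevelRow:
    score: int
    n: int
    observed_events: int
    observed_rate: float
    ci_low: float
    ci_high: float
    expected_rate: float
    within_ci: bool

    def to_dict(self) -> dict:
        return {"score": self.score, "n": self.n,
                "observed_events": self.observed_events,
                "observed_rate": self.observed_rate, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "expected_rate": self.expected_rate,
                "within_ci": self.within_ci}


@dataclass(frozen=True)
class CalibrationReport:
    """Hosmer-Lemeshow result plus per-score-level observed/expected rows.

    The levels_within/levels_total summary counts only levels with at least
    one observed event; ``pct_population_within`` is the fraction of all
    records sitting at event-containing, within-CI levels.
    """

    hl_statistic: float
    hl_df: int
    hl_p: float
    rows: tuple[ScoreLevelRow, ...]
    levels_within: int
    levels_total: int
    pct_levels_within: float
    pct_population_within: float

    def to_dict(self) -> dict:
        return {"hl_statistic": self.hl_statistic, "hl_df": self.hl_df,
                "hl_p": self.hl_p,
                "levels_within": self.levels_within,
                "levels_total": self.levels_total,
                "pct_levels_within": self.pct_levels_within,
                "pct_population_within": self.pct_population_within,
                "rows": [r.to_dict() for r in self.rows]}


def calibration_by_score(scores, y, map: ScoreRiskMap, level: float = 0.95,
                         hl_groups: int = 10) -> CalibrationReport:
    """Per-score-level calibration against the score-to-risk map.

    A level is "within" when the map's expected rate falls inside the exact
    CI around the level's observed rate.
    """
    scores = np.asarray(scores)
    if not np.all(scores == scores.astype(int)):
        raise ValidationError("scores must be integer-valued", field="scores")
    scores = scores.astype(int)
    y = as_binary(y)
    preds = risk_from_score(scores, map)
    hl = hosmer_lemeshow(preds, y, groups=min(hl_groups, max(2, len(np.unique(preds)))))

    rows = []
    n_total = len(y)
    n_within_pop = 0
    levels_total = 0
    levels_within = 0
    for s in np.unique(scores):
        mask = scores == s
        n = int(mask.sum())
        obs = int(y[mask].sum())
        rate = obs / n
        lo, hi = exact_binomial_ci(obs, n, level)
        exp_rate = float(risk_from_score(int(s), map))
        within = bool(lo <= exp_rate <= hi)
        rows.append(ScoreLevelRow(score=int(s), n=n, observed_events=obs,
                                  observed_rate=rate, ci_low=lo, ci_high=hi,
                                  expected_rate=exp_rate, within_ci=within))
        if obs >= 1:
            levels_total += 1
            if within:
                levels_within += 1
                n_within_pop += n
    return CalibrationReport(
        hl_statistic=hl.statistic, hl_df=hl.df, hl_p=hl.p_value,
        rows=tuple(rows),
        levels_within=levels_within, levels_total=levels_total,
        pct_levels_within=(percent(levels_within, levels_total)
                           if levels_total else float("nan")),
        pct_population_within=percent(n_within_pop, n_total))


# ---------------------------------------------------------------------------
# legacy comparator index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DurationCutpoints:
    """Per-procedure-prefix 75th-percentile operation durations (hours),
    with a whole-cohort fallback for unseen prefixes."""

    by_prefix: dict
    fallback: float

    @classmethod
    def from_cohort(cls, records: pd.DataFrame, q: float = 0.75) -> "DurationCutpoints":
        prefix = records["cpt_code"].str[:3]
        by = (records["duration_hours"].groupby(prefix).quantile(q)).to_dict()
        return cls(by_prefix=by, fallback=float(records["duration_hours"].quantile(q)))

    def cutpoint(self, cpt_code: str) -> float:
        prefix = validate_cpt_code(cpt_code)[:3]
        return float(self.by_prefix.get(prefix, self.fallback))


def nnis_index(record, cutpoints: DurationCutpoints) -> int:
    """Legacy basic risk index in {0,1,2,3}: one point each for ASA >= 3, a
    contaminated/dirty wound, and duration above the procedure cutpoint."""
    get = (record.get if hasattr(record, "get")
           else lambda k: getattr(record, k))
    asa = int(get("asa_class"))
    wound = get("wound_class")
    duration = float(get("duration_hours"))
    code = get("cpt_code")
    pts = int(asa >= 3)
    pts += int(wound in ("contaminated", "dirty"))
    pts += int(duration > cutpoints.cutpoint(code))
    return pts


def nnis_scores(records: pd.DataFrame, cutpoints: DurationCutpoints) -> np.ndarray:
    cut = np.array([cutpoints.cutpoint(c) for c in records["cpt_code"]])
    pts = (records["asa_class"].to_numpy(int) >= 3).astype(int)
    pts += records["wound_class"].isin(["contaminated", "dirty"]).to_numpy(int)
    pts += (records["duration_hours"].to_numpy(float) > cut).astype(int)
    return pts
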