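"""Two-stage risk-model derivation.

Stage 1: forward-selection binomial logistic regression over patient and
surgical covariates (continuous covariates enter through their selected
fractional-polynomial form). The stage-1 model then prices each 3-digit
procedure-code group by its observed/expected event ratio (the CPT3 score,
with 0/1 defaults for zero-event groups). Stage 2 repeats forward selection
with the CPT3 score added to the candidate pool at a stringent threshold and
tests a configured list of a-priori interactions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from scipy.special import expit
from scipy.stats import chi2

from ._errors import (CollinearityError, ConvergenceError,
                      DegenerateOutcomeError, ValidationError)
from ._util import as_binary
from .design import (BinaryTerm, CategoricalTerm, ContinuousTerm,
                     InteractionTerm, build_design, term_from_dict)
from .fracpoly import fp_select_detail
from .reporting import percent
from .synthetic import validate_cpt_code

logger = logging.getLogger(__name__)

MODEL_FORMAT = "ssirs-model"
MODEL_VERSION = 1
CPT3_FORMAT = "ssirs-cpt3-table"

# Expected-count threshold separating the two zero-event group defaults.
CPT3_ZERO_EVENT_THRESHOLD = 0.5
CPT3_UNSEEN_DEFAULT = 1.0


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedTerm:
    term: object
    coefs: tuple[float, ...]
    wald_p: tuple[float, ...]
    se: tuple[float, ...] = ()
    entry_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "term": self.term.to_dict(),
            "coefs": list(self.coefs),
            "wald_p": list(self.wald_p),
            "se": list(self.se),
            "entry_p": self.entry_p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedTerm":
        return cls(term=term_from_dict(d["term"]), coefs=tuple(d["coefs"]),
                   wald_p=tuple(d["wald_p"]), se=tuple(d.get("se", ())),
                   entry_p=d.get("entry_p"))


@dataclass(frozen=True)
class FittedRiskModel:
    """A fitted logistic risk model: intercept plus a list of fitted terms.

    Self-contained for prediction: each term carries the recipe (levels,
    frozen FP transform) needed to rebuild its design columns on new data.
    """

    intercept: float
    terms: tuple[FittedTerm, ...]
    converged: bool
    deviance: float
    n_obs: int
    n_events: int
    diagnostic: str | None = None

    def __post_init__(self):
        names = [ft.term.name for ft in self.terms]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate term names in model", field="terms")

    @property
    def term_names(self) -> list[str]:
        return [ft.term.name for ft in self.terms]

    def term_for(self, name: str) -> FittedTerm:
        for ft in self.terms:
            if ft.term.name == name:
                return ft
        raise KeyError(name)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(df), self.intercept)
        for ft in self.terms:
            lp += ft.term.columns(df) @ np.asarray(ft.coefs)
        return lp

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(df))

    def to_dict(self) -> dict:
        return {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "intercept": self.intercept,
            "converged": self.converged,
            "deviance": self.deviance,
            "n_obs": self.n_obs,
            "n_events": self.n_events,
            "diagnostic": self.diagnostic,
            "terms": [ft.to_dict() for ft in self.terms],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "FittedRiskModel":
        if d.get("format") != MODEL_FORMAT:
            raise ValidationError("not a model JSON document", field="format")
        return cls(intercept=d["intercept"],
                   terms=tuple(FittedTerm.from_dict(t) for t in d["terms"]),
                   converged=d["converged"], deviance=d["deviance"],
                   n_obs=d["n_obs"], n_events=d["n_events"],
                   diagnostic=d.get("diagnostic"))

    @classmethod
    def from_json(cls, path) -> "FittedRiskModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def summary_text(self) -> str:
        lines = [f"logistic model: n={self.n_obs}, events={self.n_events}, "
                 f"deviance={self.deviance:.2f}, converged={self.converged}",
                 f"  intercept          {self.intercept:+.4f}"]
        for ft in self.terms:
            for lab, c, p in zip(ft.term.labels(), ft.coefs, ft.wald_p):
                lines.append(f"  {lab:<30s} {c:+.4f}  (Wald p={p:.3g})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    if X.shape[1] <= 1:
        return
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = (diag.max() if diag.size else 0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [labels[j] for j in sorted(piv[rank:])]
        raise CollinearityError(
            f"design matrix is rank deficient; collinear columns: {bad}",
            columns=bad)


def _glm_fit(X: np.ndarray, y: np.ndarray, labels: list[str]):
    """IRLS logistic fit with separation/convergence diagnostics."""
    from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                                 PerfectSeparationWarning)

    Xc = np.column_stack([np.ones(len(y)), X])
    _check_rank(Xc, ["(intercept)"] + list(labels))
    diagnostic = None
    with warnings.catch_warnings(record=True) as caught, \
            np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        warnings.simplefilter("always")
        try:
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(
                maxiter=200, tol=1e-10)
        except PerfectSeparationError as exc:
            raise ConvergenceError(f"perfect separation: {exc}") from exc
    converged = bool(getattr(res, "converged", True))
    for w in caught:
        if issubclass(w.category, PerfectSeparationWarning):
            converged = False
            diagnostic = "perfect separation detected"
    if not converged and diagnostic is None:
        diagnostic = "IRLS did not converge"
    return res, converged, diagnostic


def _fit_terms(df: pd.DataFrame, y: np.ndarray, terms,
               entry_p: dict | None = None) -> FittedRiskModel:
    X, labels = build_design(df, terms)
    res, converged, diagnostic = _glm_fit(X, y, labels)
    params = np.asarray(res.params)
    pvals = np.asarray(res.pvalues)
    bse = np.asarray(res.bse)
    fitted_terms = []
    pos = 1
    for t in terms:
        k = len(t.labels())
        fitted_terms.append(FittedTerm(
            term=t,
            coefs=tuple(params[pos:pos + k]),
            wald_p=tuple(pvals[pos:pos + k]),
            se=tuple(bse[pos:pos + k]),
            entry_p=(entry_p or {}).get(t.name)))
        pos += k
    return FittedRiskModel(
        intercept=float(params[0]),
        terms=tuple(fitted_terms),
        converged=converged,
        deviance=float(res.deviance),
        n_obs=int(len(y)),
        n_events=int(y.sum()),
        diagnostic=diagnostic)


def fit_logistic(design, y) -> FittedRiskModel:
    """Maximum-likelihood logistic regression on a plain design matrix.

    ``design`` is a DataFrame (columns become linear terms) or a 2-D array.
    An intercept is always added. Constant outcomes raise
    :class:`DegenerateOutcomeError`; rank deficiency raises
    :class:`CollinearityError` listing the collinear columns; perfect
    separation is flagged via ``converged=False``/``diagnostic``.
    """
    y = as_binary(y)
    if y.sum() in (0, len(y)):
        raise DegenerateOutcomeError("outcome is constant; no MLE exists")
    if isinstance(design, pd.DataFrame):
        df = design.astype(float)
    else:
        arr = np.asarray(design, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        df = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
    if len(df) != len(y):
        raise ValidationError("design and outcome must be row-aligned", field="y")
    terms = [ContinuousTerm(c) for c in df.columns]
    return _fit_terms(df, y, terms)


# ---------------------------------------------------------------------------
# cohort split
# ---------------------------------------------------------------------------

def split_cohort(records: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random half split; with an odd count, derivation gets the extra row."""
    if len(records) == 0:
        raise ValidationError("cannot split an empty cohort", field="records")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    n_deriv = (len(records) + 1) // 2
    deriv = records.iloc[np.sort(perm[:n_deriv])].reset_index(drop=True)
    valid = records.iloc[np.sort(perm[n_deriv:])].reset_index(drop=True)
    return deriv, valid


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    """A covariate eligible for forward selection."""

    name: str
    kind: str  # "binary" | "categorical" | "continuous"
    levels: tuple | None = None

    def base_term(self, df: pd.DataFrame):
        if self.kind == "binary":
            return BinaryTerm(self.name)
        if self.kind == "categorical":
            levels = self.levels
            if levels is None:
                levels = tuple(sorted(pd.unique(df[self.name])))
            return CategoricalTerm(self.name, tuple(levels))
        if self.kind == "continuous":
            return ContinuousTerm(self.name, None)
        raise ValidationError(f"unknown candidate kind {self.kind!r}",
                              field=self.name)


def _candidate_entry(df, y, X_cur, dev_cur, cand: Candidate, fp_alpha: float,
                     fp_max_degree: int):
    """Return (term, entry_p) for one candidate against the working model."""
    adjustment = X_cur if X_cur.shape[1] else None
    if cand.kind == "continuous":
        res = fp_select_detail(df[cand.name].to_numpy(float), y,
                               adjustment=adjustment, alpha=fp_alpha,
                               variable=cand.name, max_degree=fp_max_degree)
        if res.decision == "omit":
            return None, res.p_overall
        term = ContinuousTerm(cand.name,
                              None if res.decision == "linear" else res.transform)
        df_cols = 1 if res.decision == "linear" else res.transform.degree
        p = float(chi2.sf(max(res.dev_null - res.entry_deviance, 0.0), df_cols))
        return term, p
    term = cand.base_term(df)
    cols = term.columns(df)
    Xnew = cols if adjustment is None else np.column_stack([adjustment, cols])
    res, converged, _ = _glm_fit(Xnew, y, ["c"] * Xnew.shape[1])
    if not converged:
        raise ConvergenceError(f"candidate {cand.name!r} caused separation")
    p = float(chi2.sf(max(dev_cur - res.deviance, 0.0), cols.shape[1]))
    return term, p


def forward_select(records: pd.DataFrame, candidates, p_entry: float = 0.05,
                   locked=(), outcome: str = "ssi30",
                   fp_alpha: float | None = None,
                   fp_max_degree: int = 2) -> FittedRiskModel:
    """Forward stepwise selection by likelihood-ratio p-value.

    At each step every remaining candidate is tested against the working
    model (categorical covariates as whole indicator blocks, multi-df;
    continuous covariates via their closed-test fractional-polynomial form);
    the smallest p-value enters if below ``p_entry``. Ties break toward the
    alphabetically first candidate name. Candidates that induce collinearity
    or separation are skipped with a logged warning.
    """
    if not list(candidates):
        raise ValidationError("candidate list is empty", field="candidates")
    y = as_binary(records[outcome])
    if y.sum() in (0, len(y)):
        raise DegenerateOutcomeError("outcome is constant")
    if fp_alpha is None:
        fp_alpha = p_entry

    terms = [c.base_term(records) for c in locked]
    entry_p: dict[str, float] = {}
    remaining = sorted(candidates, key=lambda c: c.name)
    current = _fit_terms(records, y, terms, entry_p)

    while remaining:
        X_cur, _ = build_design(records, terms)
        best: tuple[float, Candidate, object] | None = None
        for cand in remaining:
            try:
                term, p = _candidate_entry(records, y, X_cur, current.deviance,
                                           cand, fp_alpha, fp_max_degree)
            except CollinearityError:
                logger.warning("candidate %s skipped: collinear with model",
                               cand.name)
                continue
            except ConvergenceError as exc:
                logger.warning("candidate %s skipped: %s", cand.name, exc)
                continue
            if term is None:
                continue
            if best is None or p < best[0]:
                best = (p, cand, term)
        if best is None or best[0] >= p_entry:
            break
        p, cand, term = best
        terms.append(term)
        entry_p[cand.name] = p
        remaining = [c for c in remaining if c.name != cand.name]
        current = _fit_terms(records, y, terms, entry_p)
    return current


# ---------------------------------------------------------------------------
# CPT3 table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cpt3Row:
    prefix: str
    n_operations: int
    observed_ssi: int
    expected_ssi: float
    score: float
    provenance: str  # "ratio" | "default_zero" | "default_one"


@dataclass
class Cpt3Table:
    """Observed/expected event ratio per 3-digit procedure-code prefix."""

    rows: dict[str, Cpt3Row] = field(default_factory=dict)

    def lookup(self, cpt_code: str) -> tuple[float, str]:
        """Score for a full 5-character code; unseen prefixes get the
        risk-neutral default 1.0 with provenance ``unseen_default``."""
        prefix = validate_cpt_code(cpt_code)[:3]
        row = self.rows.get(prefix)
        if row is None:
            return CPT3_UNSEEN_DEFAULT, "unseen_default"
        return row.score, row.provenance

    def scores_for(self, codes) -> np.ndarray:
        return np.array([self.lookup(c)[0] for c in codes])

    def summary(self, n_possible: int | None = None) -> dict:
        """Group accounting in the reporting format: counts and percentages
        of prefixes observed / zero-defaulted / one-defaulted, against the
        number of possible prefixes."""
        n_obs_groups = len(self.rows)
        if n_possible is None:
            n_possible = n_obs_groups
        n_zero = sum(1 for r in self.rows.values() if r.provenance == "default_zero")
        n_one = sum(1 for r in self.rows.values() if r.provenance == "default_one")
        scores = np.array([r.score for r in self.rows.values()])
        return {
            "n_possible_groups": n_possible,
            "n_groups_with_operations": n_obs_groups,
            "pct_groups_with_operations": percent(n_obs_groups, n_possible),
            "n_default_zero": n_zero,
            "pct_default_zero": percent(n_zero, n_possible),
            "n_default_one": n_one,
            "pct_default_one": percent(n_one, n_possible),
            "score_min": float(scores.min()) if scores.size else None,
            "score_max": float(scores.max()) if scores.size else None,
            "score_mean": float(scores.mean()) if scores.size else None,
            "score_median": float(np.median(scores)) if scores.size else None,
        }

    def to_frame(self) -> pd.DataFrame:
        recs = [vars(r) for r in sorted(self.rows.values(), key=lambda r: r.prefix)]
        return pd.DataFrame(recs, columns=["prefix", "n_operations", "observed_ssi",
                                           "expected_ssi", "score", "provenance"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {"format": CPT3_FORMAT, "version": MODEL_VERSION,
                "rows": [vars(r) for r in
                         sorted(self.rows.values(), key=lambda r: r.prefix)]}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "Cpt3Table":
        if d.get("format") != CPT3_FORMAT:
            raise ValidationError("not a CPT3 table JSON document", field="format")
        return cls(rows={r["prefix"]: Cpt3Row(**r) for r in d["rows"]})

    @classmethod
    def from_json(cls, path) -> "Cpt3Table":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def cpt3_score_rule(observed: int, expected: float) -> tuple[float, str]:
    """Observed/expected ratio with the zero-event defaults: score 0 when no
    events were observed but more than 0.5 were expected, else score 1."""
    if observed > 0:
        return observed / expected, "ratio"
    if expected > CPT3_ZERO_EVENT_THRESHOLD:
        return 0.0, "default_zero"
    return 1.0, "default_one"


def compute_cpt3_table(records: pd.DataFrame, stage1: FittedRiskModel,
                       outcome: str = "ssi30") -> Cpt3Table:
    """Price each 3-digit prefix group by its O/E ratio under the stage-1
    model. Sum of expected over groups equals the sum of fitted
    probabilities over the cohort (conservation)."""
    for rid, code in zip(records.get("record_id", records.index), records["cpt_code"]):
        if not (isinstance(code, str) and len(code) == 5 and code[:3].isdigit()):
            raise ValidationError(
                f"record {rid!r} has unparsable CPT code {code!r}",
                field="cpt_code")
    p = stage1.predict_proba(records)
    y = as_binary(records[outcome])
    prefix = records["cpt_code"].str[:3]
    table = Cpt3Table()
    grouped = pd.DataFrame({"prefix": prefix, "y": y, "p": p}).groupby("prefix")
    for pre, g in grouped:
        observed = int(g["y"].sum())
        expected = float(g["p"].sum())
        score, prov = cpt3_score_rule(observed, expected)
        table.rows[pre] = Cpt3Row(prefix=pre, n_operations=len(g),
                                  observed_ssi=observed, expected_ssi=expected,
                                  score=float(score), provenance=prov)
    return table


def lookup_cpt3(cpt_code: str, table: Cpt3Table) -> float:
    """Score for a 5-character code (1.0 for prefixes absent from the table)."""
    return table.lookup(cpt_code)[0]


def add_cpt3_column(records: pd.DataFrame, table: Cpt3Table,
                    column: str = "cpt3_score") -> pd.DataFrame:
    out = records.copy()
    out[column] = table.scores_for(records["cpt_code"])
    return out


# ---------------------------------------------------------------------------
# stage 2
# ---------------------------------------------------------------------------

def derive_final_model(records: pd.DataFrame, table: Cpt3Table, candidates,
                       interactions=(), p_entry: float = 1e-4,
                       outcome: str = "ssi30",
                       fp_max_degree: int = 2) -> FittedRiskModel:
    """Stage-2 model: forward selection over candidates plus the CPT3 score
    (itself a continuous, FP-eligible covariate), then likelihood-ratio tests
    of each configured interaction, retained at ``p_entry`` only when both
    main effects are in the model (hierarchy enforced).
    """
    df = add_cpt3_column(records, table)
    cands = list(candidates)
    if not any(c.name == "cpt3_score" for c in cands):
        cands.append(Candidate("cpt3_score", "continuous"))
    model = forward_select(df, cands, p_entry=p_entry, outcome=outcome,
                           fp_max_degree=fp_max_degree)

    y = as_binary(df[outcome])
    base_terms = [ft.term for ft in model.terms]
    entry_p = {ft.term.name: ft.entry_p for ft in model.terms}
    retained = []
    in_model = set(model.term_names)
    for a, b in interactions:
        if a not in in_model or b not in in_model:
            logger.info("interaction %s:%s skipped (main effect missing)", a, b)
            continue
        inter = InteractionTerm(model.term_for(a).term, model.term_for(b).term)
        try:
            trial = _fit_terms(df, y, base_terms + retained + [inter])
        except (CollinearityError, ConvergenceError) as exc:
            logger.warning("interaction %s skipped: %s", inter.name, exc)
            continue
        prev_dev = (_fit_terms(df, y, base_terms + retained).deviance
                    if retained else model.deviance)
        k = len(inter.labels())
        p = float(chi2.sf(max(prev_dev - trial.deviance, 0.0), k))
        if p < p_entry:
            retained.append(inter)
            entry_p[inter.name] = p
    if retained:
        model = _fit_terms(df, y, base_terms + retained, entry_p)
    return model


def retention_summary(model: FittedRiskModel, domains: dict[str, list[str]]) -> dict:
    """Per-domain retention table: of the candidates in each named domain,
    how many entered the model, as count and percentage."""
    selected = set(model.term_names)
    out = {}
    for domain, names in domains.items():
        n_in = sum(1 for n in names if n in selected)
        out[domain] = {"n_candidates": len(names), "n_retained": n_in,
                       "pct_retained": percent(n_in, len(names))}
    return out
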