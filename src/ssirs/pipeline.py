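"""End-to-end orchestration: simulate/load -> split -> stage-1 model ->
CPT3 table -> stage-2 model -> point table -> score-risk map -> evaluation
on the held-out validation half only."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import SsirsError, ValidationError
from ._util import as_binary
from .derivation import (Candidate, Cpt3Table, FittedRiskModel,
                         add_cpt3_column, compute_cpt3_table,
                         derive_final_model, forward_select, retention_summary,
                         split_cohort)
from .design import ContinuousTerm
from .evaluation import (CalibrationReport, DurationCutpoints, c_statistic,
                         calibration_by_score, hosmer_lemeshow, nnis_scores)
from .io import PipelineConfig, read_cohort, write_cohort
from .reporting import percent
from .scoring import (PRESET_BOUNDARIES, PointScoreTable, build_point_table,
                      fit_score_risk_map, score_cohort)
from .synthetic import (ANAESTHESIA, ASA_CLASSES, FUNCTIONAL_STATUS, SETTINGS,
                        SEXES, WOUND_CLASSES, default_config, generate_cohort)

logger = logging.getLogger(__name__)


def standard_candidates() -> list[Candidate]:
    """Forward-selection candidates for the standard cohort schema."""
    return [
        Candidate("age", "continuous"),
        Candidate("sex", "categorical", SEXES),
        Candidate("bmi", "continuous"),
        Candidate("smoker", "binary"),
        Candidate("functional_status", "categorical", FUNCTIONAL_STATUS),
        Candidate("peripheral_vascular_disease", "binary"),
        Candidate("metastatic_cancer", "binary"),
        Candidate("chronic_steroid_use", "binary"),
        Candidate("preop_sepsis", "binary"),
        Candidate("setting", "categorical", SETTINGS),
        Candidate("wound_class", "categorical", WOUND_CLASSES),
        Candidate("asa_class", "categorical", ASA_CLASSES),
        Candidate("anaesthesia", "categorical", ANAESTHESIA),
        Candidate("multiple_procedures", "binary"),
        Candidate("housestaff", "binary"),
        Candidate("duration_hours", "continuous"),
    ]


# covariate domains for the retention summary table
CANDIDATE_DOMAINS = {
    "patient_demographics": ["age", "sex", "bmi", "smoker", "functional_status"],
    "medical_history": ["peripheral_vascular_disease", "metastatic_cancer",
                        "chronic_steroid_use", "preop_sepsis"],
    "surgical_information": ["setting", "wound_class", "asa_class",
                             "anaesthesia", "multiple_procedures", "housestaff",
                             "duration_hours", "cpt3_score"],
}


def _quintile_boundaries(values: np.ndarray) -> list[float]:
    qs = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    uniq = sorted(set(float(q) for q in qs))
    if not uniq:
        raise ValidationError("cannot derive quantile boundaries", field="values")
    return uniq


def resolve_categorization(config_value, model: FittedRiskModel,
                           deriv_aug: pd.DataFrame) -> dict[str, list[float]]:
    """Boundary lists for every continuous covariate in the model.

    ``"quintiles"`` uses derivation-cohort quintiles; a preset name pulls
    named boundaries (quintile fallback for covariates the preset omits);
    an explicit dict is used as given (quintile fallback likewise).
    """
    explicit: dict = {}
    if isinstance(config_value, dict):
        explicit = config_value
    elif config_value != "quintiles":
        explicit = PRESET_BOUNDARIES[config_value]
    out = {}
    for ft in model.terms:
        if isinstance(ft.term, ContinuousTerm):
            name = ft.term.name
            if name in explicit:
                out[name] = sorted(float(b) for b in explicit[name])
            else:
                out[name] = _quintile_boundaries(
                    deriv_aug[name].to_numpy(float))
    return out


@dataclass
class EvaluationBundle:
    model_discrimination: dict
    ssirs_discrimination: dict
    nnis_discrimination: dict
    model_hl: dict
    calibration: CalibrationReport
    cohort_summary: dict
    retention: dict

    def to_dict(self) -> dict:
        return {
            "model_discrimination": self.model_discrimination,
            "ssirs_discrimination": self.ssirs_discrimination,
            "nnis_discrimination": self.nnis_discrimination,
            "model_hl": self.model_hl,
            "calibration": self.calibration.to_dict(),
            "cohort_summary": self.cohort_summary,
            "retention": self.retention,
        }

    def summary_text(self) -> str:
        md, sd, nd = (self.model_discrimination, self.ssirs_discrimination,
                      self.nnis_discrimination)
        cal = self.calibration
        cs = self.cohort_summary
        lines = [
            f"validation n={cs['n_validation']}, events={cs['n_events_validation']} "
            f"({cs['pct_events_validation']}%)",
            f"model c-statistic {md['c_statistic']:.3f} "
            f"(95% CI {md['ci_low']:.3f}-{md['ci_high']:.3f})",
            f"point-score c-statistic {sd['c_statistic']:.3f} "
            f"(95% CI {sd['ci_low']:.3f}-{sd['ci_high']:.3f})",
            f"legacy-index c-statistic {nd['c_statistic']:.3f}",
            f"Hosmer-Lemeshow chi2={self.model_hl['statistic']:.2f} "
            f"df={self.model_hl['df']} p={self.model_hl['p_value']:.3g}",
            f"expected rate within exact CI at {cal.levels_within} of "
            f"{cal.levels_total} event-containing score levels "
            f"({cal.pct_levels_within}%), capturing "
            f"{cal.pct_population_within}% of the validation population",
        ]
        return "\n".join(lines)


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: pd.DataFrame
    derivation: pd.DataFrame
    validation: pd.DataFrame
    stage1_model: FittedRiskModel
    cpt3_table: Cpt3Table
    final_model: FittedRiskModel
    point_table: PointScoreTable
    evaluation: EvaluationBundle
    manifest: dict


def _analysis_config(config: PipelineConfig) -> dict:
    """Config dict minus environment-only fields (output location), so the
    manifest and its hash are identical across reruns anywhere."""
    d = config.to_dict()
    d.pop("outdir", None)
    return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_analysis_config(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig,
                 candidates: list[Candidate] | None = None) -> PipelineResult:
    """Execute every stage and write the artifact bundle to ``outdir``.

    Validation records are touched only by the evaluation stage. Reruns with
    an identical config produce byte-identical JSON artifacts.
    """
    config.validate()
    if candidates is None:
        candidates = standard_candidates()
    os.makedirs(config.outdir, exist_ok=True)

    def path(name: str) -> str:
        return os.path.join(config.outdir, name)

    stage = "load"
    try:
        if config.simulate is not None:
            stage = "simulate"
            sim = config.simulate
            cohort = generate_cohort(default_config(
                n_records=sim.n_records, seed=config.seed,
                event_rate_target=sim.event_rate_target,
                n_groups=sim.n_groups, offset_sd=sim.offset_sd))
            write_cohort(cohort, path("cohort.csv"))
        else:
            cohort = read_cohort(config.cohort_csv)
        available = set(cohort.columns)
        candidates = [c for c in candidates if c.name in available]

        stage = "split"
        deriv, valid = split_cohort(cohort, config.seed)

        stage = "stage1"
        stage1 = forward_select(deriv, candidates,
                                p_entry=config.stage1_p_entry,
                                fp_max_degree=config.fp_max_degree)
        stage1.to_json(path("stage1_model.json"))

        stage = "cpt3"
        cpt3 = compute_cpt3_table(deriv, stage1)
        cpt3.to_json(path("cpt3_table.json"))
        cpt3.to_csv(path("cpt3_table.csv"))

        stage = "stage2"
        final = derive_final_model(deriv, cpt3, candidates,
                                   interactions=[tuple(p) for p in
                                                 config.interactions],
                                   p_entry=config.stage2_p_entry,
                                   fp_max_degree=config.fp_max_degree)
        final.to_json(path("final_model.json"))

        stage = "point_table"
        deriv_aug = add_cpt3_column(deriv, cpt3)
        categorization = resolve_categorization(config.categorization, final,
                                                deriv_aug)
        ref_cov = config.reference_covariate
        ref_delta = config.reference_delta
        if ref_cov not in final.term_names:
            cont = [ft.term.name for ft in final.terms
                    if isinstance(ft.term, ContinuousTerm)]
            # a real patient covariate makes a more interpretable unit than
            # the procedure-group score
            cont.sort(key=lambda n: (n == "cpt3_score", n))
            if not cont:
                raise ValidationError(
                    "final model has no continuous term to anchor the point "
                    "unit", field="reference_covariate")
            logger.warning("reference covariate %r not in model; using %r",
                           ref_cov, cont[0])
            ref_cov = cont[0]
            # configured delta is on the original covariate's scale; for the
            # substitute use a quarter of its derivation-cohort IQR
            q25, q75 = np.quantile(deriv_aug[ref_cov].to_numpy(float),
                                   [0.25, 0.75])
            ref_delta = max((q75 - q25) / 4.0, 1e-6)
        table = build_point_table(final, deriv_aug, categorization,
                                  reference_covariate=ref_cov,
                                  reference_delta=ref_delta)

        stage = "score_risk_map"
        deriv_scores = score_cohort(deriv, deriv_aug["cpt3_score"], table)
        risk_map = fit_score_risk_map(deriv_scores, deriv["ssi30"])
        table.risk_map = risk_map
        table.to_json(path("point_table.json"))
        with open(path("point_card.txt"), "w") as fh:
            fh.write(table.card_text() + "\n")

        stage = "evaluate"
        valid_aug = add_cpt3_column(valid, cpt3)
        y_valid = as_binary(valid["ssi30"])
        model_pred = final.predict_proba(valid_aug)
        valid_scores = score_cohort(valid, valid_aug["cpt3_score"], table)
        cutpoints = DurationCutpoints.from_cohort(deriv)
        nnis = nnis_scores(valid, cutpoints)

        model_disc = c_statistic(model_pred, y_valid, config.ci_level)
        ssirs_disc = c_statistic(valid_scores, y_valid, config.ci_level)
        nnis_disc = c_statistic(nnis, y_valid, config.ci_level)
        hl = hosmer_lemeshow(model_pred, y_valid, config.hl_groups)
        calib = calibration_by_score(valid_scores, y_valid, risk_map,
                                     level=config.ci_level,
                                     hl_groups=config.hl_groups)

        n_events_valid = int(y_valid.sum())
        cohort_summary = {
            "n_total": int(len(cohort)),
            "n_derivation": int(len(deriv)),
            "n_validation": int(len(valid)),
            "n_events_total": int(cohort["ssi30"].sum()),
            "pct_events_total": percent(int(cohort["ssi30"].sum()), len(cohort)),
            "n_events_validation": n_events_valid,
            "pct_events_validation": percent(n_events_valid, len(valid)),
        }
        evaluation = EvaluationBundle(
            model_discrimination=model_disc.to_dict(),
            ssirs_discrimination=ssirs_disc.to_dict(),
            nnis_discrimination=nnis_disc.to_dict(),
            model_hl={"statistic": hl.statistic, "df": hl.df,
                      "p_value": hl.p_value},
            calibration=calib,
            cohort_summary=cohort_summary,
            retention=retention_summary(final, CANDIDATE_DOMAINS))
        with open(path("evaluation.json"), "w") as fh:
            json.dump(evaluation.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(path("evaluation.txt"), "w") as fh:
            fh.write(evaluation.summary_text() + "\n")

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "config": _analysis_config(config),
            "config_hash": _config_hash(config),
            "cpt3_summary": cpt3.summary(),
            "cohort_summary": cohort_summary,
            "versions": _versions(),
        }
        with open(path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except SsirsError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return PipelineResult(config=config, cohort=cohort, derivation=deriv,
                          validation=valid, stage1_model=stage1,
                          cpt3_table=cpt3, final_model=final,
                          point_table=table, evaluation=evaluation,
                          manifest=manifest)


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__
    return {"ssirs": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__}
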