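import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ssirs._errors import (CollinearityError, DegenerateOutcomeError,
                           ValidationError)
from ssirs._util import as_binary
from ssirs.derivation import (Candidate, Cpt3Row, Cpt3Table, FittedRiskModel,
                              FittedTerm, add_cpt3_column, compute_cpt3_table,
                              cpt3_score_rule, derive_final_model,
                              fit_logistic, forward_select, lookup_cpt3,
                              retention_summary, split_cohort)
from ssirs.design import BinaryTerm, CategoricalTerm, ContinuousTerm


class TestSplitCohort:
    def test_even_split(self):
        df = pd.DataFrame({"v": range(10)})
        a, b = split_cohort(df, seed=0)
        assert (len(a), len(b)) == (5, 5)

    def test_odd_split_derivation_gets_extra(self):
        df = pd.DataFrame({"v": range(11)})
        a, b = split_cohort(df, seed=0)
        assert (len(a), len(b)) == (6, 5)

    def test_partition_no_overlap(self):
        df = pd.DataFrame({"v": range(101)})
        a, b = split_cohort(df, seed=4)
        assert set(a["v"]).isdisjoint(b["v"])
        assert set(a["v"]) | set(b["v"]) == set(range(101))

    def test_deterministic(self):
        df = pd.DataFrame({"v": range(20)})
        a1, b1 = split_cohort(df, seed=9)
        a2, b2 = split_cohort(df, seed=9)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            split_cohort(pd.DataFrame({"v": []}), seed=0)


class TestFitLogistic:
    def test_two_by_two_log_odds_ratio(self, rng):
        # hand-computable 2x2: coefficient equals log sample odds ratio
        x = np.repeat([0, 1], [200, 200]).astype(float)
        y = np.concatenate([np.repeat([1, 0], [30, 170]),
                            np.repeat([1, 0], [70, 130])]).astype(float)
        model = fit_logistic(x[:, None], y)
        or_hand = (70 / 130) / (30 / 170)
        assert model.terms[0].coefs[0] == pytest.approx(math.log(or_hand),
                                                        abs=1e-6)

    def test_intercept_only_is_logit_of_rate(self):
        y = np.repeat([1.0, 0.0], [25, 75])
        model = fit_logistic(np.empty((100, 0)), y)
        assert model.intercept == pytest.approx(logit(0.25), abs=1e-8)

    def test_all_zero_outcome_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(np.ones((50, 1)), np.zeros(50))

    def test_collinear_design_rejected(self):
        x = np.arange(40, dtype=float)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = (x > 20).astype(float)
        with pytest.raises(CollinearityError) as err:
            fit_logistic(X, y)
        assert err.value.columns

    def test_perfect_separation_flagged(self):
        x = np.linspace(-2, 2, 60)
        y = (x > 0).astype(float)
        model = fit_logistic(x[:, None], y)
        assert not model.converged
        assert model.diagnostic

    def test_bookkeeping_fields(self, rng):
        x = rng.normal(size=300)
        y = (rng.random(300) < expit(x)).astype(float)
        m = fit_logistic(x[:, None], y)
        assert m.n_obs == 300
        assert m.n_events == int(y.sum())
        assert m.deviance >= 0


def _selection_cohort(n, seed, true_coef=1.0, n_null=9):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"signal": rng.random(n) < 0.3})
    for i in range(n_null):
        df[f"null{i:02d}"] = rng.random(n) < 0.3
    p = expit(-2.0 + true_coef * df["signal"].to_numpy(float))
    df["ssi30"] = rng.random(n) < p
    return df


class TestForwardSelect:
    def test_no_qualifying_candidate(self):
        df = _selection_cohort(500, seed=1, true_coef=0.0, n_null=3)
        cands = [Candidate(c, "binary") for c in df.columns if c != "ssi30"]
        model = forward_select(df, cands, p_entry=1e-6)
        assert model.term_names == []

    def test_true_covariate_found_and_null_rate(self):
        reps = 40
        false_total = 0
        missed = 0
        for i in range(reps):
            df = _selection_cohort(1500, seed=200 + i)
            cands = [Candidate(c, "binary") for c in df.columns if c != "ssi30"]
            model = forward_select(df, cands, p_entry=0.05)
            names = set(model.term_names)
            if "signal" not in names:
                missed += 1
            false_total += len(names - {"signal"})
        assert missed <= 2  # coef 1.0 at n=1500 is near-certain to enter
        # expected false inclusions per run ~ 9 * 0.05 = 0.45
        mean_false = false_total / reps
        assert 0.05 < mean_false < 1.2

    def test_duplicate_covariate_enters_once(self):
        df = _selection_cohort(2000, seed=5)
        df["copy"] = df["signal"]
        cands = [Candidate("signal", "binary"), Candidate("copy", "binary")]
        model = forward_select(df, cands, p_entry=0.05)
        assert len(model.term_names) == 1

    def test_locked_terms_always_present(self):
        df = _selection_cohort(2000, seed=6)
        model = forward_select(df, [Candidate("signal", "binary")],
                               p_entry=1e-12,
                               locked=[Candidate("null00", "binary")])
        assert "null00" in model.term_names

    def test_refit_reproducibility(self, small_cohort):
        from ssirs.pipeline import standard_candidates
        cands = [c for c in standard_candidates()
                 if c.name in ("smoker", "preop_sepsis", "wound_class",
                               "duration_hours")]
        m1 = forward_select(small_cohort, cands, p_entry=0.05)
        m2 = forward_select(small_cohort, cands, p_entry=0.05)
        assert m1.term_names == m2.term_names
        assert m1.to_dict() == m2.to_dict()


def _const_model(p):
    return FittedRiskModel(intercept=float(logit(p)), terms=(),
                           converged=True, deviance=0.0, n_obs=1, n_events=1)


def _cohort_for_groups(spec):
    """spec: list of (prefix, n, observed). Returns a cohort frame."""
    rows = []
    for prefix, n, obs in spec:
        for i in range(n):
            rows.append({"record_id": f"{prefix}-{i}",
                         "cpt_code": f"{prefix}0{i % 10}",
                         "ssi30": i < obs})
    return pd.DataFrame(rows)


class TestCpt3:
    def test_zero_observed_high_expected_scores_zero(self):
        score, prov = cpt3_score_rule(observed=0, expected=0.7)
        assert (score, prov) == (0.0, "default_zero")

    def test_zero_observed_low_expected_scores_one(self):
        score, prov = cpt3_score_rule(observed=0, expected=0.3)
        assert (score, prov) == (1.0, "default_one")

    def test_direct_ratio(self):
        score, prov = cpt3_score_rule(observed=4, expected=2.0)
        assert (score, prov) == (2.0, "ratio")

    def test_table_from_cohort_with_constant_model(self):
        # expected = n * 0.1 under a constant-risk model
        df = _cohort_for_groups([("441", 7, 0), ("442", 3, 0), ("443", 20, 4)])
        table = compute_cpt3_table(df, _const_model(0.1))
        assert table.rows["441"].provenance == "default_zero"
        assert table.rows["441"].score == 0.0
        assert table.rows["442"].provenance == "default_one"
        assert table.rows["442"].score == 1.0
        assert table.rows["443"].score == pytest.approx(4 / 2.0)

    def test_expected_conservation(self, pipeline_result):
        res = pipeline_result
        total_expected = sum(r.expected_ssi for r in res.cpt3_table.rows.values())
        total_fitted = res.stage1_model.predict_proba(res.derivation).sum()
        assert total_expected == pytest.approx(total_fitted, abs=1e-6)

    def test_unparsable_code_names_record(self):
        df = _cohort_for_groups([("441", 5, 1)])
        df.loc[2, "cpt_code"] = "xx140"
        with pytest.raises(ValidationError, match="441-2"):
            compute_cpt3_table(df, _const_model(0.1))

    def test_lookup_direct_and_default(self):
        table = Cpt3Table(rows={"441": Cpt3Row("441", 10, 2, 1.5, 1.3, "ratio")})
        assert lookup_cpt3("44140", table) == 1.3
        assert table.lookup("99999") == (1.0, "unseen_default")
        with pytest.raises(ValidationError):
            lookup_cpt3("4x140", table)

    def test_summary_percentages(self):
        rows = {}
        for i in range(5):
            rows[f"10{i}"] = Cpt3Row(f"10{i}", 10, 1, 0.9, 1.11, "ratio")
        rows["200"] = Cpt3Row("200", 10, 0, 0.8, 0.0, "default_zero")
        rows["201"] = Cpt3Row("201", 4, 0, 0.3, 1.0, "default_one")
        s = Cpt3Table(rows=rows).summary(n_possible=10)
        assert s["pct_groups_with_operations"] == 70.0
        assert s["pct_default_zero"] == 10.0
        assert s["pct_default_one"] == 10.0

    def test_json_roundtrip(self, tmp_path, pipeline_result):
        path = tmp_path / "t.json"
        pipeline_result.cpt3_table.to_json(path)
        loaded = Cpt3Table.from_json(path)
        assert loaded.to_dict() == pipeline_result.cpt3_table.to_dict()


class TestDeriveFinalModel:
    def test_cpt3_selected_with_increasing_effect(self, pipeline_result):
        final = pipeline_result.final_model
        assert "cpt3_score" in final.term_names
        ft = final.term_for("cpt3_score")
        lo = ft.term.contribution(0.5, np.asarray(ft.coefs))
        hi = ft.term.contribution(2.0, np.asarray(ft.coefs))
        assert hi > lo

    def test_no_interactions_equals_forward_selection(self, small_cohort):
        from ssirs.pipeline import standard_candidates
        deriv, _ = split_cohort(small_cohort, seed=1)
        stage1 = forward_select(deriv, standard_candidates(), p_entry=0.05)
        table = compute_cpt3_table(deriv, stage1)
        m_plain = derive_final_model(deriv, table, standard_candidates(),
                                     interactions=(), p_entry=0.001)
        aug = add_cpt3_column(deriv, table)
        cands = standard_candidates() + [Candidate("cpt3_score", "continuous")]
        m_fwd = forward_select(aug, cands, p_entry=0.001)
        assert m_plain.to_dict() == m_fwd.to_dict()

    def test_builtin_interaction_retained(self):
        # covariates from the generator, outcome redrawn with a strong
        # wound x duration interaction on top of both main effects
        from ssirs.synthetic import default_config, generate_cohort
        rng = np.random.default_rng(77)
        df = generate_cohort(default_config(30_000, seed=77, n_groups=30))
        dirty = df["wound_class"].isin(["contaminated", "dirty"]).to_numpy(float)
        logdur = np.log(df["duration_hours"].to_numpy(float) + 0.05)
        lp = -3.6 + 0.7 * dirty + 0.5 * logdur + 1.2 * dirty * logdur
        df["ssi30"] = rng.random(len(df)) < expit(lp)
        cands = [Candidate("wound_class", "categorical",
                           ("clean", "clean_contaminated", "contaminated",
                            "dirty")),
                 Candidate("duration_hours", "continuous"),
                 Candidate("smoker", "binary")]
        stage1 = forward_select(df, cands, p_entry=0.05)
        table = compute_cpt3_table(df, stage1)
        final = derive_final_model(
            df, table, cands,
            interactions=[("wound_class", "duration_hours")], p_entry=1e-4)
        assert "wound_class:duration_hours" in final.term_names
        # hierarchy: both main effects present
        assert {"wound_class", "duration_hours"} <= set(final.term_names)

    def test_two_stage_c_not_worse(self, pipeline_result):
        from ssirs.evaluation import c_statistic
        res = pipeline_result
        valid_aug = add_cpt3_column(res.validation, res.cpt3_table)
        y = as_binary(res.validation["ssi30"])
        c1 = c_statistic(res.stage1_model.predict_proba(res.validation), y)
        c2 = c_statistic(res.final_model.predict_proba(valid_aug), y)
        assert c2.c_statistic >= c1.c_statistic - 0.02


class TestModelSerialization:
    def test_json_roundtrip_preserves_predictions(self, tmp_path,
                                                  pipeline_result):
        res = pipeline_result
        path = tmp_path / "model.json"
        res.final_model.to_json(path)
        loaded = FittedRiskModel.from_json(path)
        valid_aug = add_cpt3_column(res.validation, res.cpt3_table)
        assert np.allclose(loaded.predict_proba(valid_aug),
                           res.final_model.predict_proba(valid_aug))

    def test_duplicate_terms_rejected(self):
        t = FittedTerm(BinaryTerm("a"), (0.1,), (0.5,))
        with pytest.raises(ValidationError):
            FittedRiskModel(intercept=0.0, terms=(t, t), converged=True,
                            deviance=1.0, n_obs=10, n_events=2)


def test_retention_summary_format():
    model = FittedRiskModel(
        intercept=-3.0,
        terms=(FittedTerm(BinaryTerm("smoker"), (0.3,), (0.01,)),
               FittedTerm(ContinuousTerm("duration_hours"), (0.5,), (0.001,))),
        converged=True, deviance=10.0, n_obs=100, n_events=10)
    out = retention_summary(model, {"surgical": ["duration_hours", "setting"],
                                    "patient": ["smoker"]})
    assert out["surgical"] == {"n_candidates": 2, "n_retained": 1,
                               "pct_retained": 50.0}
    assert out["patient"]["pct_retained"] == 100.0
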