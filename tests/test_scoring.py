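import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ssirs._errors import ValidationError
from ssirs._util import round_half_away
from ssirs.derivation import FittedRiskModel, FittedTerm, add_cpt3_column
from ssirs.design import BinaryTerm, CategoricalTerm, ContinuousTerm
from ssirs.scoring import (PointScoreTable, ScoreRiskMap, build_point_table,
                           fit_score_risk_map, nnt, risk_from_score,
                           score_cohort, ssirs_score)


def _toy_model(bmi_coef=0.04, smoker_coef=None, wound_coefs=(0.2, 0.5, 0.9)):
    terms = [FittedTerm(ContinuousTerm("bmi"), (bmi_coef,), (0.001,))]
    if smoker_coef is not None:
        terms.append(FittedTerm(BinaryTerm("smoker"), (smoker_coef,), (0.001,)))
    terms.append(FittedTerm(
        CategoricalTerm("wound_class",
                        ("clean", "clean_contaminated", "contaminated",
                         "dirty")),
        tuple(wound_coefs), (0.001,) * 3))
    return FittedRiskModel(intercept=-4.0, terms=tuple(terms), converged=True,
                           deviance=100.0, n_obs=1000, n_events=40)


def _toy_data(rng, n=2000):
    return pd.DataFrame({
        "bmi": rng.normal(28, 6, n).clip(15, None),
        "smoker": rng.random(n) < 0.2,
        "wound_class": rng.choice(
            ["clean", "clean_contaminated", "contaminated", "dirty"], n),
    })


class TestBuildPointTable:
    def test_binary_coef_exactly_one_unit(self, rng):
        # bmi linear coef 0.04 -> B = 0.04 * 5 = 0.2
        model = _toy_model(smoker_coef=0.2)
        table = build_point_table(model, _toy_data(rng), {"bmi": [25, 30, 35]})
        entry = table.entry_for("smoker")
        yes = next(c for c in entry.categories if c.level is True)
        assert table.reference_unit == pytest.approx(0.2)
        assert yes.points == 1

    def test_binary_coef_two_point_four_units_rounds_to_two(self, rng):
        model = _toy_model(smoker_coef=0.2 * 2.4)
        table = build_point_table(model, _toy_data(rng), {"bmi": [25, 30, 35]})
        yes = next(c for c in table.entry_for("smoker").categories
                   if c.level is True)
        assert yes.points == 2

    def test_all_categories_match_bruteforce_oracle(self, rng):
        model = _toy_model(smoker_coef=0.37)
        data = _toy_data(rng)
        table = build_point_table(model, data, {"bmi": [22, 27, 31, 36]})
        B = table.reference_unit

        # independent recomputation: round(beta * (W_ij - W_ref) / B)
        for entry in table.entries:
            ft = model.term_for(entry.covariate)
            ref = next(c for c in entry.categories if c.is_reference)
            for cat in entry.categories:
                if entry.kind == "continuous":
                    beta = ft.coefs[0]
                    expected = round_half_away(
                        beta * (cat.representative - ref.representative) / B)
                elif entry.kind == "binary":
                    expected = (0 if cat.level is False
                                else round_half_away(ft.coefs[0] / B))
                else:
                    if cat.is_reference:
                        expected = 0
                    else:
                        levels = ft.term.levels
                        beta = ft.coefs[levels[1:].index(cat.level)]
                        expected = round_half_away(beta / B)
                assert cat.points == expected, (entry.covariate, cat.label)

    def test_score_range_is_sum_of_extremes(self, rng):
        model = _toy_model(smoker_coef=0.5)
        table = build_point_table(model, _toy_data(rng), {"bmi": [25, 30, 35]})
        lo = sum(e.min_points for e in table.entries)
        hi = sum(e.max_points for e in table.entries)
        assert table.score_range == (lo, hi)

    def test_zero_reference_coefficient_rejected(self, rng):
        model = _toy_model(bmi_coef=0.0, smoker_coef=0.5)
        with pytest.raises(ValidationError, match="unit"):
            build_point_table(model, _toy_data(rng), {"bmi": [25, 30, 35]})

    def test_unmodeled_covariate_in_categorization_rejected(self, rng):
        model = _toy_model()
        with pytest.raises(ValidationError, match="age"):
            build_point_table(model, _toy_data(rng),
                              {"bmi": [25, 30], "age": [50]})

    def test_exactly_one_reference_per_covariate(self, rng):
        model = _toy_model(smoker_coef=0.5)
        table = build_point_table(model, _toy_data(rng), {"bmi": [25, 30, 35]})
        for entry in table.entries:
            assert sum(c.is_reference for c in entry.categories) == 1


class TestSsirsScore:
    def test_all_reference_record_scores_base_constant(self, rng):
        model = _toy_model(smoker_coef=0.5)
        data = _toy_data(rng)
        table = build_point_table(model, data, {"bmi": [25, 30, 35]},
                                  base_constant=3)
        ref_bmi = next(c for c in table.entry_for("bmi").categories
                       if c.is_reference)
        record = {"bmi": ref_bmi.representative, "smoker": False,
                  "wound_class": "clean"}
        assert ssirs_score(record, 1.0, table) == 3

    def test_score_within_declared_range(self, pipeline_result):
        res = pipeline_result
        aug = add_cpt3_column(res.validation, res.cpt3_table)
        scores = score_cohort(res.validation, aug["cpt3_score"],
                              res.point_table)
        lo, hi = res.point_table.score_range
        assert scores.min() >= lo and scores.max() <= hi

    def test_matches_independent_oracle(self, rng):
        model = _toy_model(smoker_coef=0.45)
        data = _toy_data(rng)
        table = build_point_table(model, data, {"bmi": [25, 30, 35]})
        sample = _toy_data(np.random.default_rng(5), n=1000)

        def oracle(row):
            total = 0
            for entry in table.entries:
                val = row[entry.covariate]
                if entry.kind == "continuous":
                    for c in entry.categories:
                        lo = -math.inf if c.lower is None else c.lower
                        hi = math.inf if c.upper is None else c.upper
                        if lo < val <= hi:
                            total += c.points
                            break
                else:
                    total += next(c.points for c in entry.categories
                                  if c.level == val)
            return total

        for _, row in sample.iterrows():
            assert ssirs_score(row, 1.0, table) == oracle(row)

    def test_unknown_level_rejected(self, rng):
        model = _toy_model(smoker_coef=0.45)
        table = build_point_table(model, _toy_data(rng), {"bmi": [25, 30]})
        with pytest.raises(ValidationError, match="wound_class"):
            ssirs_score({"bmi": 28.0, "smoker": False,
                         "wound_class": "sterile"}, 1.0, table)

    def test_json_roundtrip_identical_scores(self, tmp_path, pipeline_result):
        res = pipeline_result
        path = tmp_path / "points.json"
        res.point_table.to_json(path)
        loaded = PointScoreTable.from_json(path)
        aug = add_cpt3_column(res.validation.head(200), res.cpt3_table)
        s1 = score_cohort(res.validation.head(200), aug["cpt3_score"],
                          res.point_table)
        s2 = score_cohort(res.validation.head(200), aug["cpt3_score"], loaded)
        assert np.array_equal(s1, s2)


class TestScoreRiskMap:
    def test_binary_scores_closed_form(self):
        # scores {0,1} with event rates p0, p1: beta = logit(p1) - logit(p0)
        scores = np.repeat([0, 1], [400, 400])
        y = np.concatenate([np.repeat([1.0, 0.0], [40, 360]),
                            np.repeat([1.0, 0.0], [120, 280])])
        m = fit_score_risk_map(scores, y)
        assert m.beta == pytest.approx(logit(0.3) - logit(0.1), abs=1e-6)
        assert m.intercept == pytest.approx(logit(0.1), abs=1e-6)

    def test_null_beta_near_zero(self, rng):
        scores = rng.integers(0, 10, 4000)
        y = (rng.random(4000) < 0.1).astype(float)
        m = fit_score_risk_map(scores, y)
        # 3 SE of a null slope at this n is well under 0.1
        assert abs(m.beta) < 0.1

    def test_constant_scores_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            fit_score_risk_map(np.ones(100), np.repeat([1.0, 0.0], [10, 90]))

    def test_perfect_separation_flagged(self):
        scores = np.repeat([0, 1], [50, 50])
        m = fit_score_risk_map(scores, scores.astype(float))
        assert not m.converged

    def test_risk_from_score_examples(self):
        m = ScoreRiskMap(intercept=0.0, beta=0.0)
        assert risk_from_score(17, m) == pytest.approx(0.5)
        m = ScoreRiskMap(intercept=-3.0, beta=0.2)
        risks = risk_from_score(np.arange(-10, 30), m)
        assert np.all(np.diff(risks) > 0)
        assert risk_from_score(5, m) == pytest.approx(expit(-3.0 + 1.0))

    def test_self_consistency_with_fit(self, rng):
        scores = rng.integers(0, 15, 3000)
        y = (rng.random(3000) < expit(-3 + 0.15 * scores)).astype(float)
        m = fit_score_risk_map(scores, y)
        import statsmodels.api as sm
        X = np.column_stack([np.ones(3000), scores])
        fitted = sm.GLM(y, X, family=sm.families.Binomial()).fit().fittedvalues
        assert np.allclose(risk_from_score(scores, m), fitted, atol=1e-6)


class TestNNT:
    def test_baseline_ten_percent_halving(self):
        assert nnt(0.10, 0.5) == pytest.approx(20.0)

    def test_baseline_one_percent_halving(self):
        assert nnt(0.01, 0.5) == pytest.approx(200.0)

    def test_no_effect_is_infinite(self):
        assert math.isinf(nnt(0.10, 1.0))

    def test_harm_signaled_distinctly(self):
        with pytest.raises(ValidationError, match="harm"):
            nnt(0.10, 1.5)

    def test_invalid_baseline(self):
        with pytest.raises(ValidationError):
            nnt(0.0, 0.5)


def test_integer_score_discrimination_not_better_than_model(pipeline_result):
    from ssirs._util import as_binary
    from ssirs.evaluation import c_statistic

    res = pipeline_result
    aug = add_cpt3_column(res.validation, res.cpt3_table)
    y = as_binary(res.validation["ssi30"])
    c_model = c_statistic(res.final_model.predict_proba(aug), y).c_statistic
    scores = score_cohort(res.validation, aug["cpt3_score"], res.point_table)
    c_score = c_statistic(scores, y).c_statistic
    assert c_score <= c_model + 1e-12


def test_card_text_lists_all_categories(pipeline_result):
    card = pipeline_result.point_table.card_text()
    for entry in pipeline_result.point_table.entries:
        assert entry.covariate in card
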