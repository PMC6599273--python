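"""Logistic model, radiomics score, bootstrap evaluation and nomogram tests."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.base import clone

from mwradiomics.models import (BootstrapLogisticModel, build_nomogram,
                                combine_clinical, evaluate, fit_logistic,
                                radiomics_score, roc_curve_table,
                                youden_threshold)
from mwradiomics.selection import rank_auroc


class TestFitLogistic:
    def test_two_by_two_odds_ratio_closed_form(self):
        # cell counts 20,10 / 10,20: OR = (20*20)/(10*10) = 4
        x = np.repeat([0, 0, 1, 1], [20, 10, 10, 20])
        y = np.repeat([0, 1, 0, 1], [20, 10, 10, 20])
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert m.odds_ratios["x"] == pytest.approx(4.0, rel=1e-6)

    def test_intercept_only_balanced(self):
        y = np.repeat([0, 1], 30)
        m = fit_logistic(pd.DataFrame(index=range(60)), y, covariates=[])
        assert m.intercept == pytest.approx(0.0, abs=1e-8)
        assert m.predict_proba(pd.DataFrame(index=range(3)))[0] == pytest.approx(0.5)

    def test_coefficient_consistency_simulation(self):
        rng = np.random.default_rng(31)
        n = 2000
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < expit(1.0 * x)).astype(int)
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        se = float(m._result.bse["x"])
        assert abs(m.coefficients["x"] - 1.0) <= 3 * se

    def test_separation_flagged_not_fatal(self):
        y = np.repeat([0, 1], 20)
        x = y.astype(float)  # perfect separation
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert m.separation_flagged

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"x": [0.0, 1.0]}), [0, 1])


class TestRadiomicsScore:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(32)
        n = 300
        X = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
        y = (rng.random(n) < expit(0.8 * X["a"] - 0.5 * X["b"])).astype(int)
        return X, y, fit_logistic(X, y)

    def test_zero_covariates_give_intercept(self, fitted):
        X, _, m = fitted
        z = pd.DataFrame({"a": [0.0], "b": [0.0]})
        assert radiomics_score(m, z)[0] == pytest.approx(m.intercept)

    def test_refit_invariance(self, fitted):
        """Refitting a logistic model on the score reproduces the original
        predicted probabilities to 1e-8 (slope 1, intercept 0)."""
        X, y, m = fitted
        score = radiomics_score(m, X)
        refit = fit_logistic(pd.DataFrame({"s": score}), y)
        p_orig = m.predict_proba(X)
        p_refit = refit.predict_proba(pd.DataFrame({"s": score}))
        assert np.abs(p_orig - p_refit).max() < 1e-8

    def test_unit_increase_multiplies_odds_by_exp_beta(self, fitted):
        X, _, m = fitted
        z0 = pd.DataFrame({"a": [1.0], "b": [2.0]})
        z1 = pd.DataFrame({"a": [2.0], "b": [2.0]})
        odds = lambda p: p / (1 - p)
        ratio = odds(m.predict_proba(z1)[0]) / odds(m.predict_proba(z0)[0])
        assert ratio == pytest.approx(math.exp(m.coefficients["a"]))

    def test_missing_covariate_named(self, fitted):
        _, _, m = fitted
        with pytest.raises(ValueError, match="b"):
            radiomics_score(m, pd.DataFrame({"a": [0.0]}))


class TestCombineClinical:
    def test_planted_sex_effect_recovered(self):
        rng = np.random.default_rng(33)
        n = 1500
        sex = rng.integers(0, 2, n)
        copd = rng.integers(0, 2, n)
        score = rng.normal(0, 1, n)
        beta_sex = math.log(5.0)
        y = (rng.random(n) < expit(-0.5 + beta_sex * sex + 0.8 * score)).astype(int)
        clin = pd.DataFrame({"sex_female": sex, "copd": copd})
        m = combine_clinical(score, clin, y)
        se = float(m._result.bse["sex_female"])
        assert abs(m.coefficients["sex_female"] - beta_sex) <= 3 * se
        assert m.coefficients["radiomics_score"] > 0

    def test_null_clinical_rarely_significant(self):
        rng = np.random.default_rng(34)
        hits = 0
        for _ in range(10):
            n = 200
            score = rng.normal(0, 1, n)
            y = (rng.random(n) < expit(score)).astype(int)
            clin = pd.DataFrame({"sex_female": rng.integers(0, 2, n),
                                 "copd": rng.integers(0, 2, n)})
            m = combine_clinical(score, clin, y)
            hits += (m.pvalues[["sex_female", "copd"]] < 0.05).any()
        assert hits <= 2  # ~5% per covariate under the null


class TestEvaluate:
    def test_four_point_worked_example(self):
        """AUROC of scores (0.1, 0.4, 0.35, 0.8) vs labels (0,0,1,1) is 0.75:
        3 of the 4 discordant-label pairs are correctly ordered."""
        perf = evaluate(np.array([0.1, 0.4, 0.35, 0.8]),
                        np.array([0, 0, 1, 1]), n_boot=100, seed=0)
        assert perf.auroc == pytest.approx(0.75)

    def test_perfect_separation_statistics(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        perf = evaluate(scores, y, n_boot=100, seed=0)
        assert perf.auroc == 1.0
        assert perf.sensitivity == 1.0 and perf.specificity == 1.0
        assert perf.accuracy == 1.0

    def test_permuted_labels_ci_covers_half(self):
        rng = np.random.default_rng(35)
        covered = 0
        for _ in range(10):
            scores = rng.normal(0, 1, 80)
            y = rng.permutation(np.repeat([0, 1], 40))
            perf = evaluate(scores, y, n_boot=200, seed=1)
            covered += perf.auroc_ci[0] <= 0.5 <= perf.auroc_ci[1]
        assert covered >= 9

    def test_pair_counting_oracle_matches_rank_formula(self):
        rng = np.random.default_rng(36)
        scores = rng.normal(0, 1, 60)
        y = rng.integers(0, 2, 60)
        # exhaustive pair counting with tie credit
        num, den = 0.0, 0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                den += 1
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j]:
                    num += 0.5
        assert rank_auroc(scores, y)[0] == pytest.approx(num / den)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(37)

        def width(n):
            x = rng.normal(0, 1, n)
            y = (rng.random(n) < expit(1.5 * x)).astype(int)
            p = evaluate(x, y, n_boot=300, seed=2)
            return p.auroc_ci[1] - p.auroc_ci[0]

        assert width(800) < width(60)

    def test_roc_table_endpoints(self):
        t = roc_curve_table(np.array([0.1, 0.9]), np.array([0, 1]))
        assert t.iloc[0].tpr == 0.0 and t.iloc[-1].fpr == 1.0

    def test_youden_threshold_maximizes_j(self):
        scores = np.array([0.1, 0.2, 0.6, 0.7, 0.8])
        y = np.array([0, 0, 0, 1, 1])
        t = youden_threshold(scores, y)
        assert t == pytest.approx(0.7)


class TestNomogram:
    def test_single_covariate_spans_full_scale(self):
        rng = np.random.default_rng(38)
        X = pd.DataFrame({"a": rng.uniform(0, 2, 100)})
        y = (rng.random(100) < expit(2.0 * (X["a"] - 1))).astype(int)
        m = fit_logistic(X, y)
        spec = build_nomogram(m, X)
        pts = spec.points("a", X["a"])
        assert pts.min() == pytest.approx(0.0)
        assert pts.max() == pytest.approx(100.0)
        # probability curve equals the inverse logit of the model
        p = spec.probability(spec.total_points(X))
        assert np.abs(p - m.predict_proba(X)).max() < 1e-9

    def test_point_scale_proportional_to_beta_times_range(self):
        from mwradiomics.models import FittedModel
        model = FittedModel(covariates=["a", "b"], intercept=-1.0,
                            coefficients=pd.Series({"a": 2.0, "b": 1.0}),
                            odds_ratios=pd.Series({"a": math.exp(2), "b": math.e}),
                            pvalues=pd.Series({"a": 0.01, "b": 0.02}))
        X = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 1.0]})  # equal ranges
        spec = build_nomogram(model, X)
        assert spec.points("a", 1.0) == pytest.approx(100.0)
        assert spec.points("b", 1.0) == pytest.approx(50.0)

    def test_round_trip_probability_reconstruction(self):
        rng = np.random.default_rng(39)
        n = 200
        X = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.uniform(-2, 2, n),
                          "c": rng.integers(0, 2, n).astype(float)})
        y = (rng.random(n) < expit(X["a"] - 0.7 * X["b"] + 0.4 * X["c"])).astype(int)
        m = fit_logistic(X, y)
        spec = build_nomogram(m, X)
        p = spec.probability(spec.total_points(X))
        assert np.abs(p - m.predict_proba(X)).max() <= 1e-6

    def test_negative_coefficient_reference_at_max(self):
        from mwradiomics.models import FittedModel
        model = FittedModel(covariates=["a"], intercept=0.0,
                            coefficients=pd.Series({"a": -1.0}),
                            odds_ratios=pd.Series({"a": math.exp(-1)}),
                            pvalues=pd.Series({"a": 0.01}))
        X = pd.DataFrame({"a": [0.0, 4.0]})
        spec = build_nomogram(model, X)
        assert spec.reference["a"] == 4.0
        assert spec.points("a", 0.0) == pytest.approx(100.0)

    def test_zero_range_covariate_excluded_with_warning(self):
        from mwradiomics.models import FittedModel
        model = FittedModel(covariates=["a", "flat"], intercept=0.0,
                            coefficients=pd.Series({"a": 1.0, "flat": 2.0}),
                            odds_ratios=pd.Series({"a": math.e, "flat": math.exp(2)}),
                            pvalues=pd.Series({"a": 0.01, "flat": 0.5}))
        X = pd.DataFrame({"a": [0.0, 1.0], "flat": [3.0, 3.0]})
        with pytest.warns(UserWarning, match="zero observed range"):
            spec = build_nomogram(model, X)
        assert spec.covariates == ["a"]
        # the constant covariate still contributes to the base predictor
        p = spec.probability(spec.total_points(X))
        assert p[0] == pytest.approx(expit(1.0 * 0.0 + 2.0 * 3.0))


class TestBootstrapLogisticModel:
    def test_sklearn_classifier_api(self):
        rng = np.random.default_rng(40)
        X = pd.DataFrame({"a": rng.normal(0, 1, 120)})
        y = (rng.random(120) < expit(2 * X["a"])).astype(int)
        m = clone(BootstrapLogisticModel(n_boot=100, random_state=0)).fit(X, y)
        assert set(m.classes_) == {0, 1}
        proba = m.predict_proba(X)
        assert proba.shape == (120, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (m.predict(X) == (proba[:, 1] >= 0.5).astype(int)).all()
        perf = m.performance(X, y)
        assert 0.5 < perf.auroc <= 1.0

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            BootstrapLogisticModel().fit(pd.DataFrame({"a": range(9)}),
                                         [0, 1, 2] * 3)
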