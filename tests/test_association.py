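"""Descriptive group tables and JIVE-score logistic regressions."""

import numpy as np
import pandas as pd
import pytest

from actijive import association
from actijive.association import (descriptive_table, jive_logistic,
                                  logistic_table, pooled_mean, pooled_percent)


def make_cohort(rng, n=600, beta=None, confound=False):
    """Scores + covariates with an optional planted per-SD log-OR vector."""
    scores = pd.DataFrame(rng.standard_normal((n, 9)),
                          columns=[f"Joint-{i}" for i in (1, 2, 3)]
                          + ["SL-1", "PA-1", "PA-2", "CR-1", "CR-2", "CR-3"])
    scores = (scores - scores.mean()) / scores.std(ddof=1)
    age = rng.normal(60, 10, n)
    if confound:
        scores["Joint-1"] += 0.05 * (age - 60)
        scores["Joint-1"] = (scores["Joint-1"] - scores["Joint-1"].mean()) \
            / scores["Joint-1"].std(ddof=1)
    eta = np.zeros(n)
    if beta:
        for k, v in beta.items():
            eta += v * scores[k].to_numpy()
    if confound:
        eta += 0.05 * (age - 60)
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    cov = pd.DataFrame({
        "age": age,
        "sex": np.where(rng.random(n) < 0.54, "female", "male"),
        "bmi": rng.normal(26, 4, n),
        "group": np.where(y, np.where(rng.random(n) < 0.16, "current", "remitted"),
                          "none"),
        "anxiety": rng.random(n) < 0.05,
        "sud": rng.random(n) < 0.01,
        "medication": rng.random(n) < 0.10,
    }, index=scores.index)
    return scores, cov


class TestPooling:
    def test_weighted_mean_hand_arithmetic(self):
        assert pooled_mean({"a": 10.0, "b": 20.0}, {"a": 3, "b": 1}) \
            == pytest.approx(12.5)

    def test_percent_uses_total_denominator(self):
        assert pooled_percent({"a": 30, "b": 10}, {"a": 100, "b": 100}) \
            == pytest.approx(20.0)


class TestDescriptiveTable:
    def test_identical_groups_are_null(self):
        base = pd.DataFrame({"x": np.tile([1.0, 2, 3, 4], 2),
                             "sex": ["female", "male"] * 4,
                             "group": ["a"] * 4 + ["b"] * 4})
        out = descriptive_table(base, "group", categorical=["sex"],
                                continuous=["x"])
        cont = out[out["variable"] == "x"].iloc[0]
        assert cont["statistic"] == pytest.approx(0.0)
        assert cont["p_value"] == pytest.approx(1.0)
        cat = out[out["variable"] == "sex"].iloc[0]
        assert cat["p_value"] == pytest.approx(1.0)

    def test_planted_two_sd_shift_detected(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "x": np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1, 100)]),
            "group": ["a"] * 100 + ["b"] * 100})
        out = descriptive_table(df, "group", continuous=["x"])
        assert out.iloc[0]["p_value"] < 1e-3

    def test_tiny_group_gets_missing_p(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "group": ["a", "a", "a", "b"]})
        out = descriptive_table(df, "group", continuous=["x"])
        assert np.isnan(out.iloc[0]["p_value"])

    def test_single_group_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2], "group": ["a", "a"]})
        with pytest.raises(ValueError):
            descriptive_table(df, "group", continuous=["x"])


class TestLogistic:
    def test_null_scores_give_unit_odds_ratios(self):
        rng = np.random.default_rng(1)
        scores, cov = make_cohort(rng, n=5000)
        res = jive_logistic(scores, cov, "lifetime")
        assert res.converged
        tab = res.table.set_index("predictor")
        assert ((tab["OR"] > 0.9) & (tab["OR"] < 1.1)).all()
        assert ((tab["ci_low"] <= 1.0) & (tab["ci_high"] >= 1.0)).sum() >= 8

    def test_planted_log_odds_recovered(self):
        rng = np.random.default_rng(2)
        scores, cov = make_cohort(rng, n=4000, beta={"Joint-1": np.log(0.7)})
        res = jive_logistic(scores, cov, "lifetime")
        row = res.table.set_index("predictor").loc["Joint-1"]
        assert row["ci_low"] < 0.7 < row["ci_high"]

    def test_contrasts_are_separate_fits_with_correct_ns(self):
        rng = np.random.default_rng(3)
        scores, cov = make_cohort(rng, n=800)
        for contrast in ("lifetime", "current", "remitted"):
            res = jive_logistic(scores, cov, contrast)
            cases = cov["group"].isin(association.CONTRASTS[contrast]).sum()
            assert res.n_case == cases
            assert res.n_control == (cov["group"] == "none").sum()
        with pytest.raises(ValueError):
            jive_logistic(scores, cov, "acute")

    def test_estimates_invariant_to_score_order(self):
        rng = np.random.default_rng(4)
        scores, cov = make_cohort(rng, n=1000, beta={"PA-2": -0.3})
        a = jive_logistic(scores, cov, "lifetime").table.set_index("predictor")
        b = jive_logistic(scores[scores.columns[::-1]], cov,
                          "lifetime").table.set_index("predictor")
        for p in scores.columns:
            assert a.loc[p, "OR"] == pytest.approx(b.loc[p, "OR"], rel=1e-8)

    def test_confounded_design_needs_adjustment(self):
        rng = np.random.default_rng(5)
        scores, cov = make_cohort(rng, n=6000, confound=True)
        adj = jive_logistic(scores, cov, "lifetime")
        unadj = jive_logistic(scores, cov, "lifetime", covariates=())
        or_adj = adj.table.set_index("predictor").loc["Joint-1", "OR"]
        or_unadj = unadj.table.set_index("predictor").loc["Joint-1", "OR"]
        # no direct score effect was planted: adjusted OR near 1, unadjusted
        # inflated through the age path
        assert abs(np.log(or_adj)) < abs(np.log(or_unadj)) - 0.05
        assert or_adj == pytest.approx(1.0, abs=0.15)

    def test_medication_covariate_optional(self):
        rng = np.random.default_rng(6)
        scores, cov = make_cohort(rng, n=800)
        res = jive_logistic(scores, cov, "lifetime", with_medication=True)
        assert "medication" in res.covariates

    def test_fitted_probabilities_average_to_rate(self):
        """Score equation of the intercept: refitting the reported
        coefficients reproduces the observed outcome rate."""
        import statsmodels.api as sm
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("abc"))
        y = rng.random(500) < 0.3
        res = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=0)
        assert res.predict().mean() == pytest.approx(y.mean(), abs=1e-8)
        tab, conv, _ = logistic_table(X, y)
        assert conv

    def test_separation_is_flagged_not_silent(self):
        X = pd.DataFrame({"a": np.concatenate([np.full(50, -2.0), np.full(50, 2.0)])})
        y = X["a"] > 0
        tab, conv, warn = logistic_table(X, y)
        assert not conv
        assert warn

    def test_bh_column_is_monotone_adjustment(self):
        rng = np.random.default_rng(8)
        scores, cov = make_cohort(rng, n=2000, beta={"Joint-1": -0.4})
        tab = jive_logistic(scores, cov, "lifetime").table
        assert (tab["p_bh"] >= tab["p"] - 1e-12).all()
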