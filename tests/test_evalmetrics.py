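"""Evaluation metrics against exhaustive-pair and generic-optimizer oracles:
horizon AUC with the censoring exclusion rule, c-index, Breslow Cox
regression, quartile Kaplan-Meier risk groups, added-value comparison."""

import numpy as np
import pandas as pd
import pytest

from _oracles import c_index_pairs, cox_fit_oracle, horizon_auc_pairs
from histoprog import evalmetrics as ev
from histoprog.core import CENSOR_ADMIN, CENSOR_DISEASE, CENSOR_NONDISEASE


def make_records(times, events, reasons=None, **extra):
    events = np.asarray(events, dtype=bool)
    if reasons is None:
        reasons = np.where(events, CENSOR_DISEASE, CENSOR_ADMIN)
    df = pd.DataFrame({
        "case_id": [f"c{i}" for i in range(len(times))],
        "time_months": np.asarray(times, dtype=int),
        "event": events,
        "censor_reason": reasons,
    })
    for k, v in extra.items():
        df[k] = v
    return df


def random_records(rng, n):
    times = rng.integers(1, 100, size=n)
    events = rng.random(n) < 0.5
    reasons = np.where(
        events, CENSOR_DISEASE,
        np.where(rng.random(n) < 0.5, CENSOR_NONDISEASE, CENSOR_ADMIN),
    )
    return make_records(times, events, reasons), rng.normal(size=n)


class TestFiveYearAUC:
    def test_perfect_ranking_and_constant_scores(self):
        rec = make_records([10, 20, 80, 90], [1, 1, 0, 0])
        s = np.array([4.0, 3.0, 2.0, 1.0])
        assert ev.five_year_auc(s, rec, n_boot=0)["auc"] == 1.0
        assert ev.five_year_auc(np.zeros(4), rec, n_boot=0)["auc"] == 0.5

    def test_constructed_six_case_table(self):
        # 2 events <= 60, 3 survivors past 60, 1 excluded (non-disease at 40)
        rec = make_records(
            [12, 55, 40, 70, 90, 61],
            [1, 1, 0, 0, 0, 0],
            [CENSOR_DISEASE, CENSOR_DISEASE, CENSOR_NONDISEASE,
             CENSOR_ADMIN, CENSOR_ADMIN, CENSOR_ADMIN],
        )
        s = np.array([2.0, 0.5, 9.9, 1.0, 0.0, 0.5])
        out = ev.five_year_auc(s, rec, n_boot=0)
        # pairs: (2 vs 1,0,.5)->1,1,1 ; (.5 vs 1,0,.5)->0,1,.5 => 4.5/6
        assert out["auc"] == pytest.approx(4.5 / 6)
        assert out["n_excluded"] == 1 and out["n_pos"] == 2 and out["n_neg"] == 3

    def test_exclusion_accounting_partition(self):
        rng = np.random.default_rng(0)
        rec, _ = random_records(rng, 200)
        pos, neg, excl = ev.horizon_classes(rec)
        assert (pos.astype(int) + neg.astype(int) + excl.astype(int) == 1).all()
        expected_excl = (~rec["event"] & (rec["time_months"] < 60)).to_numpy()
        assert np.array_equal(excl, expected_excl)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            n = int(rng.integers(3, 9))
            rec, s = random_records(rng, n)
            if rng.random() < 0.4:  # force score ties
                s = np.round(s)
            try:
                oracle = horizon_auc_pairs(s, rec["time_months"], rec["event"],
                                           rec["censor_reason"])
            except ValueError:
                with pytest.raises(ValueError):
                    ev.five_year_auc(s, rec, n_boot=0)
                continue
            assert ev.five_year_auc(s, rec, n_boot=0)["auc"] == pytest.approx(oracle)

    def test_event_at_horizon_is_positive(self):
        rec = make_records([60, 90], [1, 0])
        out = ev.five_year_auc(np.array([1.0, 0.0]), rec, n_boot=0)
        assert out["n_pos"] == 1 and out["auc"] == 1.0


class TestCIndex:
    def test_negative_time_scores_give_perfect_concordance(self):
        t = np.array([5, 10, 20, 40])
        rec = make_records(t, [1, 1, 1, 1])
        assert ev.c_index(-t.astype(float), rec, n_boot=0)["c_index"] == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        rec, s = random_records(rng, 800)
        assert abs(ev.c_index(s, rec, n_boot=0)["c_index"] - 0.5) < 0.05

    def test_five_case_censored_example(self):
        rec = make_records([3, 5, 5, 9, 12], [1, 0, 1, 1, 0])
        s = np.array([3.0, 1.0, 2.0, 2.0, 0.0])
        # admissible: (0,1)(0,2)(0,3)(0,4) conc; (2,3) tie .5 -> wait times 5==5 not admissible
        oracle = c_index_pairs(s, [3, 5, 5, 9, 12], [1, 0, 1, 1, 0])
        assert ev.c_index(s, rec, n_boot=0)["c_index"] == pytest.approx(oracle)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            n = int(rng.integers(2, 9))
            rec, s = random_records(rng, n)
            if rng.random() < 0.4:
                s = np.round(s)
            try:
                oracle = c_index_pairs(s, rec["time_months"].to_numpy(),
                                       rec["event"].to_numpy())
            except ValueError:
                with pytest.raises(ValueError):
                    ev.c_index_value(s, rec["time_months"], rec["event"])
                continue
            assert ev.c_index_value(s, rec["time_months"].to_numpy(),
                                    rec["event"].to_numpy()) == pytest.approx(oracle)

    def test_agrees_with_lifelines_on_distinct_times(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(4)
        times = rng.permutation(200) + 1  # all distinct
        events = rng.random(200) < 0.6
        s = rng.normal(size=200)
        ours = ev.c_index_value(s, times, events)
        theirs = concordance_index(times, -s, events)
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestCoxFit:
    def test_two_group_rate_ratio_recovery(self):
        rng = np.random.default_rng(10)
        n = 2000
        grp = rng.integers(0, 2, size=n)
        lam = np.where(grp == 1, 0.02 * 2, 0.02)
        t = np.minimum(np.ceil(rng.exponential(1 / lam)), 120).astype(int)
        e = np.ceil(rng.exponential(1 / lam)).astype(int) <= 120
        t = np.maximum(t, 1)
        rec = make_records(t, e, group=grp.astype(str))
        fit = ev.fit_cox(rec, covariates={"group": "0"})
        hr = fit.summary.loc["group[1]", "hr"]
        assert 1.8 <= hr <= 2.2

    def test_matches_generic_optimizer_on_small_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = 10
            X = rng.normal(size=(n, 2))
            times = rng.integers(1, 6, size=n)  # forced ties
            events = rng.random(n) < 0.7
            if events.sum() < 3:
                events[:3] = True
            rec = make_records(times, events)
            fit = ev.fit_cox(rec, X=pd.DataFrame(X, columns=["a", "b"], index=rec.index))
            oracle = cox_fit_oracle(X, times, events)
            assert np.abs(fit.summary["coef"].to_numpy() - oracle).max() < 1e-4

    def test_agrees_with_lifelines_without_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(12)
        n = 150
        x = rng.normal(size=n)
        t = np.argsort(rng.random(n)) + 1  # distinct times
        e = rng.random(n) < 0.6
        rec = make_records(t, e)
        fit = ev.fit_cox(rec, X=pd.DataFrame({"x": x}, index=rec.index))
        df = pd.DataFrame({"T": t, "E": e, "x": x})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert fit.summary.loc["x", "coef"] == pytest.approx(
            cph.params_["x"], abs=1e-5
        )

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(13)
        rec, s = random_records(rng, 1500)
        fit = ev.fit_cox(rec, X=pd.DataFrame({"noise": s}, index=rec.index))
        assert fit.summary.loc["noise", "hr"] == pytest.approx(1.0, abs=0.1)
        lo, hi = fit.summary.loc["noise", ["ci_low", "ci_high"]]
        assert lo <= fit.summary.loc["noise", "hr"] <= hi

    def test_insufficient_events_and_constant_covariate_errors(self):
        rec = make_records([5, 8, 11], [1, 0, 0])
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.1, 0.5, 0.9]}, index=rec.index)
        with pytest.raises(ValueError, match="events"):
            ev.fit_cox(rec, X=X)
        rec4 = make_records([5, 8, 11, 14], [1, 1, 1, 0])
        Xc = pd.DataFrame({"a": [1.0] * 4}, index=rec4.index)
        with pytest.raises(ValueError, match="constant"):
            ev.fit_cox(rec4, X=Xc)

    def test_codings_age_per_decade_and_dummies(self):
        rng = np.random.default_rng(14)
        rec, s = random_records(rng, 120)
        rec["age"] = rng.normal(65, 10, size=120)
        rec["sex"] = rng.choice(["male", "female"], size=120)
        X, coding = ev.build_design(rec, covariates={"sex": "male"})
        assert "age_per_decade" in X.columns and "sex[female]" in X.columns
        assert "sex[male]" not in X.columns
        assert X["age_per_decade"].mean() == pytest.approx(0.0, abs=1e-9)
        assert coding["age"]["scale"] == 10.0


class TestKMRiskGroups:
    def test_quartile_thresholds_linear_interpolation(self):
        tune = np.arange(100, dtype=float)  # 0..99
        eval_scores = np.array([0.0, 30.0, 99.0])
        rec = make_records([10, 20, 30], [1, 1, 1])
        rg = ev.km_risk_groups(tune, eval_scores, rec, fit_group_cox=False)
        assert rg.thresholds == (pytest.approx(24.75), pytest.approx(74.25))
        assert list(rg.assignment) == ["low", "medium", "high"]

    def test_event_free_cohort_km_survival_is_one(self):
        rec = make_records([70, 80, 90, 100] * 3, [0] * 12)
        s = np.arange(12, dtype=float)
        rg = ev.km_risk_groups(np.arange(12, dtype=float), s, rec, fit_group_cox=False)
        for curve in rg.km_curves.values():
            assert (curve["survival"] == 1.0).all()

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(20)
        t = rng.integers(1, 50, size=40)
        rec = make_records(t, [1] * 40)
        s = rng.normal(size=40)
        rg = ev.km_risk_groups(s, s, rec, fit_group_cox=False)
        low = rec.loc[(s <= np.percentile(s, 25))]
        curve = rg.km_curves["low"]
        for month in (5, 20, 45):
            emp = (low["time_months"] > month).mean()
            km = curve.loc[curve["month"] == month, "survival"].iloc[0]
            assert km == pytest.approx(emp, abs=1e-9)

    def test_empty_extreme_group_rejected(self):
        rec = make_records([10, 20, 30], [1, 1, 1])
        with pytest.raises(ValueError, match="empty"):
            ev.km_risk_groups(np.array([0.0, 1.0]), np.array([10.0, 10.0, 10.0]), rec)


class TestAddedValue:
    def _cohort(self, rng, n, signal=0.0):
        age = rng.normal(65, 10, size=n)
        score = rng.normal(size=n)
        lam = 0.01 * np.exp(0.02 * (age - 65) + signal * score)
        t_ev = rng.exponential(1 / lam)
        t = np.maximum(np.minimum(np.ceil(t_ev), 120), 1).astype(int)
        e = t_ev <= 120
        rec = make_records(t, e, age=age)
        return rec, score

    def test_zero_weight_score_gives_zero_delta(self):
        rng = np.random.default_rng(30)
        rec, score = self._cohort(rng, 400, signal=0.0)
        out = ev.added_value_report(rec, score, rec, score, covariates={}, n_boot=0)
        # the combined model may fit noise; deltas must be tiny in-sample
        assert abs(out["delta_c_index"]) < 0.05

    def test_informative_score_adds_value(self):
        rng = np.random.default_rng(31)
        fit_rec, fit_s = self._cohort(rng, 500, signal=0.8)
        ev_rec, ev_s = self._cohort(rng, 500, signal=0.8)
        out = ev.added_value_report(fit_rec, fit_s, ev_rec, ev_s, covariates={}, n_boot=0)
        assert out["delta_auc"] > 0.05 and out["delta_c_index"] > 0.05
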