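import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.statistics import multivariate_logrank_test

from cdscore import cox_fit, cox_report, cox_score_test, km_estimate, logrank_test
from cdscore.exceptions import DesignError, ValidationError
from cdscore.simulation_studies import KM_ORACLE, LOGRANK_ORACLE


class TestKaplanMeier:
    def test_hand_oracle_to_six_decimals(self):
        km = km_estimate(KM_ORACLE["times"], KM_ORACLE["events"])
        np.testing.assert_allclose(km.survival_prob, KM_ORACLE["surv"], atol=1e-6)
        assert km.median_survival == pytest.approx(KM_ORACLE["median"])
        np.testing.assert_array_equal(km.event_times, [6, 10, 15, 25])
        np.testing.assert_array_equal(km.at_risk, [6, 4, 3, 1])

    def test_all_censored_flat_curve_median_not_reached(self):
        km = km_estimate([5.0, 8.0, 12.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.median_survival is None
        assert km.median_label == "NR"
        assert km.survival_at(100.0) == 1.0

    def test_distinct_events_closed_form(self):
        km = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        np.testing.assert_allclose(km.survival_prob, [3 / 4, 2 / 4, 1 / 4, 0.0])
        assert km.median_survival == 2.0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(30, 40)
        e = (rng.random(40) < 0.6).astype(int)
        perm = rng.permutation(40)
        a, b = km_estimate(t, e), km_estimate(t[perm], e[perm])
        np.testing.assert_allclose(a.survival_prob, b.survival_prob)
        np.testing.assert_array_equal(a.event_times, b.event_times)

    def test_empty_input_errors(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogrank:
    def test_hand_oracle(self):
        lr = logrank_test(LOGRANK_ORACLE["times"], LOGRANK_ORACLE["events"],
                          LOGRANK_ORACLE["group"])
        assert lr.chi2 == pytest.approx(LOGRANK_ORACLE["chi2"], abs=1e-9)
        assert lr.observed.sum() == pytest.approx(lr.expected.sum(), abs=1e-9)

    def test_duplicated_dataset_gives_null(self):
        t = [3.0, 7.0, 9.0, 14.0]
        e = [1, 0, 1, 1]
        lr = logrank_test(t + t, e + e, ["A"] * 4 + ["B"] * 4)
        assert lr.chi2 == pytest.approx(0.0, abs=1e-12)
        assert lr.p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(20, 30)
        e = (rng.random(30) < 0.7).astype(int)
        g = rng.choice(["A", "B"], 30)
        swapped = np.where(g == "A", "B", "A")
        a, b = logrank_test(t, e, g), logrank_test(t, e, swapped)
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_time_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        t = rng.exponential(20, n)
        e = (rng.random(n) < 0.7).astype(int)
        g = rng.choice(["A", "B"], n)
        if e.sum() == 0 or len(set(g)) < 2:
            return
        base = logrank_test(t, e, g)
        trans = logrank_test(np.exp(t / t.max() * 3), e, g)
        assert base.chi2 == pytest.approx(trans.chi2, rel=1e-10)

    @pytest.mark.parametrize("k_groups", [2, 3, 4])
    def test_agrees_with_lifelines(self, k_groups):
        rng = np.random.default_rng(k_groups)
        n = 25 * k_groups
        t = rng.exponential(30, n).round(1)      # rounding induces ties
        e = (rng.random(n) < 0.7).astype(int)
        g = rng.choice([f"g{i}" for i in range(k_groups)], n)
        mine = logrank_test(t, e, g)
        ref = multivariate_logrank_test(pd.Series(t), pd.Series(g), pd.Series(e))
        assert mine.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_requires_two_groups_and_events(self):
        with pytest.raises(DesignError):
            logrank_test([1, 2, 3], [1, 1, 1], ["A", "A", "A"])
        with pytest.raises(DesignError):
            logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["A", "A", "B", "B"])


class TestCox:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(1)
        n = 2000
        t = rng.exponential(40, n)
        e = (rng.random(n) < 0.8).astype(int)
        x = rng.permutation(np.repeat([0.0, 1.0], n // 2))
        fit = cox_fit(t, e, pd.DataFrame({"x": x}))
        assert 0.9 <= fit.hazard_ratio("x") <= 1.11

    def test_hr_equivariance_under_negation(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(40, 300)
        e = (rng.random(300) < 0.8).astype(int)
        x = rng.standard_normal(300)
        x -= x.mean()
        hr_pos = cox_fit(t, e, pd.DataFrame({"x": x})).hazard_ratio("x")
        hr_neg = cox_fit(t, e, pd.DataFrame({"x": -x})).hazard_ratio("x")
        assert abs(hr_pos * hr_neg - 1.0) < 1e-9

    def test_score_test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(8)
        n = 400
        t = rng.exponential(40, n)               # continuous: no ties
        e = (rng.random(n) < 0.75).astype(int)
        z = (rng.random(n) < 0.5).astype(float)
        chi2, p = cox_score_test(t, e, z)
        lr = logrank_test(t, e, np.where(z > 0, "hi", "lo"))
        assert chi2 == pytest.approx(lr.chi2, abs=1e-6)
        assert p == pytest.approx(lr.p_value, abs=1e-6)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_ties_methods_run_and_agree_roughly(self, ties):
        rng = np.random.default_rng(10)
        n = 200
        t = rng.exponential(30, n).round()       # month-resolution ties
        e = (rng.random(n) < 0.8).astype(int)
        x = rng.standard_normal(n)
        fit = cox_fit(t, e, pd.DataFrame({"x": x}), ties=ties)
        assert fit.ties == ties
        assert fit.converged
        lo, hi = fit.summary.loc["x", ["hr_low", "hr_high"]]
        assert lo <= fit.hazard_ratio("x") <= hi

    def test_constant_covariate_rejected(self):
        with pytest.raises(DesignError, match="constant"):
            cox_fit([1, 2, 3, 4], [1, 1, 1, 1],
                    pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]}))

    def test_separation_flagged_not_silent(self):
        # covariate = event-time rank on fully observed data: the partial
        # likelihood is maximized at an unbounded coefficient
        n = 40
        t = np.arange(1.0, n + 1)
        e = np.ones(n, dtype=int)
        x = -t / n * 40
        fit = cox_fit(t, e, pd.DataFrame({"x": x}))
        assert not fit.converged
        assert fit.flags


class TestCoxReport:
    @pytest.fixture
    def clin(self):
        rng = np.random.default_rng(3)
        n = 150
        risk = (rng.random(n) < 0.3).astype(float)
        iss = rng.integers(1, 4, n).astype(float)
        t = rng.exponential(40 / (1 + risk), n)
        return pd.DataFrame({
            "os_time": t, "os_event": (rng.random(n) < 0.8).astype(int),
            "cd_risk_high": risk, "ISS": iss,
        })

    def test_univariate_rows(self, clin):
        tab = cox_report(clin, ["cd_risk_high", "ISS"], design="univariate")
        assert set(tab["covariate"]) == {"cd_risk_high", "ISS"}
        assert (tab["hr"] > 0).all()

    def test_pairwise_blocks_include_primary(self, clin):
        tab = cox_report(clin, ["cd_risk_high", "ISS"], design="pairwise",
                         primary="cd_risk_high")
        assert (tab.groupby("block")["covariate"]
                .apply(lambda s: "cd_risk_high" in set(s)).all())

    def test_full_model_single_block(self, clin):
        tab = cox_report(clin, ["cd_risk_high", "ISS"], design="full")
        assert tab["block"].nunique() == 1

    def test_absent_covariate_skipped_with_warning(self, clin, caplog):
        with caplog.at_level("WARNING"):
            tab = cox_report(clin, ["cd_risk_high", "del17p"], design="univariate")
        assert "del17p" in caplog.text
        assert set(tab["covariate"]) == {"cd_risk_high"}
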