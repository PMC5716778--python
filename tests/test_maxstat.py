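import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdscore import bh_adjust, logrank_test, maxstat_cutpoint, maxstat_pvalue
from cdscore.exceptions import DegenerateInputError, DesignError, ValidationError
from cdscore.maxstat import SurvivalIndex, screen_prognostic
from cdscore.simulate import (
    PlantedGene,
    SyntheticTruth,
    generate_survival_cohort,
    probeset_names,
)


def _null_data(seed, n=60):
    rng = np.random.default_rng(seed)
    t = rng.exponential(40, n)
    e = (rng.random(n) < 0.7).astype(int)
    x = rng.lognormal(6, 0.5, n)
    return x, t, e


class TestMaxstatCutpoint:
    def test_constant_expression_degenerate(self):
        _, t, e = _null_data(0, 40)
        with pytest.raises(DegenerateInputError, match="constant"):
            maxstat_cutpoint(np.full(40, 3.0), t, e)

    def test_preconditions(self):
        x, t, e = _null_data(1, 10)
        with pytest.raises(DesignError, match=">= 20 subjects"):
            maxstat_cutpoint(x, t, e)
        x, t, _ = _null_data(2, 40)
        with pytest.raises(DesignError, match=">= 5 events"):
            maxstat_cutpoint(x, t, np.zeros(40, dtype=int))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        """M equals the brute-force maximum of |standardized log-rank|
        over every in-band split, scored by the independent k-sample
        log-rank implementation."""
        x, t, e = _null_data(seed, 40)
        res = maxstat_cutpoint(x, t, e)
        n = len(x)
        best, best_cut = 0.0, None
        for v in np.unique(x):
            k = int((x > v).sum())
            if 0.10 * n <= k <= 0.90 * n:
                lr = logrank_test(t, e, np.where(x > v, "high", "low"))
                stat = np.sqrt(lr.chi2)
                if stat > best + 1e-12:
                    best, best_cut = stat, v
        assert res.M == pytest.approx(best, abs=1e-9)
        assert res.cutpoint == pytest.approx(best_cut)

    def test_high_group_is_strictly_above_cutpoint(self):
        x, t, e = _null_data(3, 50)
        res = maxstat_cutpoint(x, t, e)
        n_high = (x > res.cutpoint).sum()
        assert 0.10 * 50 <= n_high <= 0.90 * 50
        assert res.cut_quantile == pytest.approx((50 - n_high) / 50)
        assert res.cutpoint in x            # cutpoint is an observed value

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        x, t, e = _null_data(seed, 45)
        base = maxstat_cutpoint(x, t, e)
        trans = maxstat_cutpoint(x**1.5, t, e)     # strictly increasing on x>0
        assert trans.M == pytest.approx(base.M, rel=1e-10)
        assert trans.direction == base.direction
        assert trans.cut_quantile == pytest.approx(base.cut_quantile)
        assert trans.cutpoint == pytest.approx(base.cutpoint**1.5)
        np.testing.assert_array_equal(x > base.cutpoint,
                                      x**1.5 > trans.cutpoint)

    def test_planted_cut_recovered(self, planted_survival_cohort):
        cohort, resolved, ps = planted_survival_cohort
        t, e = cohort.survival()
        res = maxstat_cutpoint(cohort.expression_vector(ps), t, e)
        assert res.direction == "high_good"
        assert abs(res.cut_quantile - 0.5) <= 0.1

    def test_shared_index_equals_fresh(self):
        x, t, e = _null_data(11, 60)
        idx = SurvivalIndex(t, e)
        assert maxstat_cutpoint(x, t, e, index=idx).M == \
            maxstat_cutpoint(x, t, e).M


class TestMaxstatPvalue:
    def test_zero_statistic_capped_at_one(self):
        assert maxstat_pvalue(0.0) == 1.0

    def test_monotone_on_grid(self):
        grid = np.arange(1.0, 4.01, 0.5)
        ps = [maxstat_pvalue(b) for b in grid]
        assert (np.diff(ps) < 0).all()
        assert all(0 <= p <= 1 for p in ps)

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValidationError):
            maxstat_pvalue(2.0, band=(0.5, 0.5))

    def test_wider_band_larger_p(self):
        assert maxstat_pvalue(3.0, band=(0.05, 0.95)) > \
            maxstat_pvalue(3.0, band=(0.25, 0.75))

    def test_permutation_method_agrees_for_strong_effect(
            self, planted_survival_cohort):
        cohort, _, ps = planted_survival_cohort
        t, e = cohort.survival()
        x = cohort.expression_vector(ps)
        res = maxstat_cutpoint(x, t, e)
        p_perm = maxstat_pvalue(res.M, method="permutation", expr_vector=x,
                                times=t, events=e, n_perm=200, seed=3)
        assert p_perm == pytest.approx(1 / 201)   # nothing exceeds the planted effect
        assert maxstat_pvalue(res.M_ne) < 0.001

    def test_permutation_null_moderate(self):
        x, t, e = _null_data(21, 50)
        res = maxstat_cutpoint(x, t, e)
        p_perm = maxstat_pvalue(res.M, method="permutation", expr_vector=x,
                                times=t, events=e, n_perm=200, seed=4)
        assert p_perm > 0.05


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.02])[0] == pytest.approx(0.02)

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_independent_step_up(self, ps):
        """Order-preserving step-up with monotonicity, written from the
        definition: q_(i) = min_{j>=i} p_(j) m / j."""
        ps = np.asarray(ps)
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        ranked = ps[order] * m / np.arange(1, m + 1)
        ranked = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
        expected = np.empty(m)
        expected[order] = ranked
        np.testing.assert_allclose(bh_adjust(ps), expected, atol=1e-12)

    def test_rejects_invalid(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestScreen:
    def _pair(self, seed, n=200, beta=-np.log(4.0)):
        planted = {probeset_names(40)[0]: PlantedGene(0.5, beta)}
        cohorts = []
        for j in range(2):
            truth = SyntheticTruth(planted_prognostic=planted, censor_rate=0.25,
                                   seed=seed + j)
            c, _ = generate_survival_cohort(n, 40, truth, name=f"c{j}")
            cohorts.append(c)
        return cohorts

    def test_strong_planted_gene_replicates(self):
        cohorts = self._pair(100)
        report = screen_prognostic(cohorts, probeset_names(40))
        assert probeset_names(40)[0] in report.replicated
        assert report.directions[probeset_names(40)[0]] == "high_good"
        for tab in report.per_cohort.values():
            assert (tab["p_bh"] >= tab["p_approx"] - 1e-15).all()

    def test_alpha_zero_empty(self):
        cohorts = self._pair(200)
        report = screen_prognostic(cohorts, probeset_names(40), alpha=0.0)
        assert report.replicated == []

    def test_single_cohort_warns(self, caplog):
        cohorts = self._pair(300)
        with caplog.at_level("WARNING"):
            report = screen_prognostic(cohorts[:1], probeset_names(40))
        assert "single cohort" in caplog.text
        assert probeset_names(40)[0] in report.replicated

    def test_missing_candidate_reported_and_excluded(self):
        cohorts = self._pair(400)
        ghost = "ghost_at"
        report = screen_prognostic(cohorts, probeset_names(40) + [ghost])
        assert ghost in report.missing["c0"]
        assert ghost not in report.replicated

    def test_replicated_subset_of_each_significant_set(self):
        cohorts = self._pair(500)
        report = screen_prognostic(cohorts, probeset_names(40))
        for tab in report.per_cohort.values():
            sig = set(tab.index[tab["p_bh"] < report.alpha])
            assert set(report.replicated) <= sig
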