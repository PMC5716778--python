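import numpy as np
import pandas as pd
import pytest

from cdscore import CdGeneRiskScore, CdScoreModel, assign_stage, evaluate, merge_stages
from cdscore.cohort import ClinicalTable, Cohort, ExpressionMatrix
from cdscore.exceptions import (
    BuildError,
    DesignError,
    ModelApplicationError,
    ValidationError,
)
from cdscore.simulate import (
    PlantedGene,
    SyntheticTruth,
    generate_staged_survival,
    generate_survival_cohort,
    probeset_names,
)

PUBLISHED_MERGE = {1: "high", 2: "high", 3: "low", 4: "low", 5: "low"}


def _four_gene_model(cut=100.0, merge_map=PUBLISHED_MERGE):
    genes = [("CD24", "ps_a"), ("CD27", "ps_b"), ("CD36", "ps_c"), ("CD302", "ps_d")]
    return CdScoreModel(
        gene_set=genes,
        cutpoints={ps: cut for _, ps in genes},
        merge_map=dict(merge_map),
        stage_blocks={1: 0, 2: 0, 3: 1, 4: 1, 5: 1},
        alpha_merge=0.05,
    )


def _cohort_from_rows(rows, probesets):
    n = len(rows[0])
    samples = [f"S{i}" for i in range(n)]
    expr = ExpressionMatrix(np.asarray(rows, dtype=float),
                            probeset_ids=probesets, sample_ids=samples)
    clin = ClinicalTable(pd.DataFrame({
        "sample_id": samples,
        "os_time": np.linspace(10, 90, n),
        "os_event": [1] * n,
    }))
    return Cohort(expr, clin)


class TestAssignStage:
    def test_count_stages_match_published_groups(self):
        # columns: all-below, one-above, two-above, all-above
        rows = [
            [50, 150, 150, 150],
            [50, 50, 150, 150],
            [50, 50, 50, 150],
            [50, 50, 50, 150],
        ]
        cohort = _cohort_from_rows(rows, ["ps_a", "ps_b", "ps_c", "ps_d"])
        model = _four_gene_model()
        out = assign_stage(cohort, model)
        assert out["stage"].tolist() == [1, 2, 3, 5]
        # published merge: no/one gene high -> high risk, >=2 -> low risk
        assert out["risk"].tolist() == ["high", "high", "low", "low"]

    def test_tie_at_cutpoint_counts_low(self):
        cohort = _cohort_from_rows([[100.0, 100.0001, 99.9, 101]], ["ps_a"])
        genes = [("G", "ps_a")]
        model = CdScoreModel(gene_set=genes, cutpoints={"ps_a": 100.0},
                             merge_map={1: "high", 2: "low"},
                             stage_blocks={1: 0, 2: 1}, alpha_merge=0.05)
        out = assign_stage(cohort, model)
        assert out["n_high"].tolist() == [0, 1, 0, 1]

    def test_missing_probeset_named(self):
        cohort = _cohort_from_rows([[1, 2, 3]], ["ps_a"])
        with pytest.raises(ModelApplicationError, match="ps_b"):
            assign_stage(cohort, _four_gene_model())

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        rows = rng.lognormal(4, 1, (4, 30))
        cohort = _cohort_from_rows(rows, ["ps_a", "ps_b", "ps_c", "ps_d"])
        model = _four_gene_model(cut=float(np.median(rows)))
        base = assign_stage(cohort, model)
        f = lambda v: v**2 + 1          # strictly increasing on positives
        cohort2 = _cohort_from_rows(f(rows), ["ps_a", "ps_b", "ps_c", "ps_d"])
        model2 = _four_gene_model(cut=f(float(np.median(rows))))
        trans = assign_stage(cohort2, model2)
        assert base["stage"].tolist() == trans["stage"].tolist()


class TestMergeStages:
    def test_planted_two_block_structure(self):
        stages, t, e = generate_staged_survival(
            500, [0.03, 0.03, 0.0075, 0.0075, 0.0075], censor_rate=0.25, seed=3)
        merge_map, blocks, tests = merge_stages(stages, t, e, n_stages=5)
        assert merge_map == PUBLISHED_MERGE
        assert not tests.empty

    def test_well_separated_hazards_not_merged(self):
        stages, t, e = generate_staged_survival(
            2000, [0.5, 0.1, 0.02, 0.004, 0.0008],
            stage_probs=[0.2] * 5, censor_rate=0.0, seed=4)
        merge_map, blocks, _ = merge_stages(stages, t, e, n_stages=5)
        assert len(set(blocks.values())) == 5         # five blocks retained
        # binary risk labels still contiguous: a high-risk run of low
        # stages followed by a low-risk run (hazards decrease with stage)
        risks = [merge_map[s] for s in range(1, 6)]
        k = risks.count("high")
        assert 1 <= k <= 4
        assert risks == ["high"] * k + ["low"] * (5 - k)

    def test_empty_stage_absorbed_into_lower_neighbor(self):
        rng = np.random.default_rng(5)
        stages = np.array([1] * 50 + [2] * 50 + [4] * 50 + [5] * 50)
        hazards = {1: 0.05, 2: 0.05, 4: 0.01, 5: 0.01}
        t = np.array([rng.exponential(1 / hazards[s]) for s in stages])
        merge_map, blocks, _ = merge_stages(stages, t, np.ones_like(stages),
                                            n_stages=5)
        assert blocks[3] == blocks[2]                 # empty stage 3 joins stage 2
        assert merge_map[3] == merge_map[2]

    def test_order_stability(self):
        stages, t, e = generate_staged_survival(
            400, [0.04, 0.04, 0.01, 0.01, 0.01], censor_rate=0.2, seed=6)
        m1, _, _ = merge_stages(stages, t, e, n_stages=5)
        perm = np.random.default_rng(0).permutation(len(stages))
        m2, _, _ = merge_stages(stages[perm], t[perm], e[perm], n_stages=5)
        assert m1 == m2

    @pytest.mark.parametrize("seed", range(5))
    def test_blocks_always_contiguous(self, seed):
        stages, t, e = generate_staged_survival(
            120, [0.05, 0.03, 0.02, 0.012, 0.008], censor_rate=0.3, seed=seed)
        _, blocks, _ = merge_stages(stages, t, e, n_stages=5)
        ordered = [blocks[s] for s in range(1, 6)]
        assert ordered == sorted(ordered)             # block index non-decreasing

    def test_all_empty_errors(self):
        with pytest.raises(DesignError):
            merge_stages([], [], [], n_stages=5)

    def test_high_risk_is_worse_median(self):
        stages, t, e = generate_staged_survival(
            600, [0.06, 0.06, 0.01, 0.01, 0.01], censor_rate=0.0, seed=7)
        merge_map, _, _ = merge_stages(stages, t, e, n_stages=5)
        hi = np.isin(stages, [s for s, r in merge_map.items() if r == "high"])
        assert np.median(t[hi]) < np.median(t[~hi])


class TestModelJson:
    def test_round_trip_byte_identical(self, tmp_path):
        model = _four_gene_model(cut=123.456)
        text = model.to_json()
        back = CdScoreModel.from_json(text)
        assert back.to_json() == text
        path = tmp_path / "model.json"
        model.to_json(str(path))
        assert CdScoreModel.from_json(str(path)).to_json() == text

    def test_invariants_enforced(self):
        with pytest.raises(ValidationError, match="cutpoints"):
            CdScoreModel(gene_set=[("G", "ps_a")], cutpoints={},
                         merge_map={}, stage_blocks={}, alpha_merge=0.05)
        with pytest.raises(ValidationError, match="merge_map"):
            CdScoreModel(gene_set=[("G", "ps_a")], cutpoints={"ps_a": 1.0},
                         merge_map={1: "low"}, stage_blocks={}, alpha_merge=0.05)


@pytest.fixture(scope="module")
def fitted():
    planted = {ps: PlantedGene(0.5, -np.log(3.5))
               for ps in probeset_names(50)[:2]}
    cohorts = []
    for j, name in enumerate(("train", "valid")):
        truth = SyntheticTruth(planted_prognostic=planted, censor_rate=0.25,
                               seed=40 + j)
        c, _ = generate_survival_cohort(220, 50, truth, name=name)
        cohorts.append(c)
    est = CdGeneRiskScore(cohorts[0], validation=[cohorts[1]],
                          candidates=probeset_names(50))
    return est, est.fit(seed=1), cohorts


class TestEndToEnd:
    def test_planted_genes_in_model(self, fitted):
        _, results, _ = fitted
        assert {ps for _, ps in results.model.gene_set} == set(probeset_names(50)[:2])

    def test_training_self_consistency(self, fitted):
        """Frozen-cutpoint self-application reproduces the merge-time
        stage survival exactly."""
        est, results, cohorts = fitted
        rep = results.training_evaluation
        t, _ = cohorts[0].survival()
        assignment = assign_stage(cohorts[0], results.model)
        pd.testing.assert_frame_equal(rep.assignment, assignment)
        assert rep.cutpoint_mode == "frozen"
        risks = {c.risk: c for c in rep.classes}
        for risk, stats in risks.items():
            sel = assignment["risk"] == risk
            assert stats.n == int(sel.sum())

    def test_validation_discriminates(self, fitted):
        _, results, cohorts = fitted
        rep = results.evaluate(cohorts[1])
        by = {c.risk: c for c in rep.classes}
        assert rep.logrank.p_value < 0.05
        assert rep.hazard_ratio_high > 1.0
        assert rep.hazard_ratio_low == pytest.approx(1 / rep.hazard_ratio_high)
        # high risk dies sooner: median either reached earlier or only the
        # low-risk median is "not reached"
        if by["high"].median_survival is not None and by["low"].median_survival is not None:
            assert by["high"].median_survival <= by["low"].median_survival
        else:
            assert by["low"].median_survival is None

    def test_missing_model_probeset_errors(self, fitted):
        _, results, cohorts = fitted
        keep = [p for p in probeset_names(50)
                if p != results.model.gene_set[0][1]]
        reduced = Cohort(
            ExpressionMatrix(cohorts[1].expression.values.loc[keep]),
            cohorts[1].clinical, class_labels=cohorts[1].class_labels,
            name="reduced")
        with pytest.raises(ModelApplicationError):
            results.evaluate(reduced)

    def test_unfrozen_model_rejected(self, fitted):
        _, results, cohorts = fitted
        bare = CdScoreModel(gene_set=results.model.gene_set,
                            cutpoints=results.model.cutpoints,
                            merge_map={}, stage_blocks={}, alpha_merge=0.05)
        with pytest.raises(ModelApplicationError, match="merge_map"):
            evaluate(cohorts[1], bare)

    def test_summary_mentions_genes_and_risk(self, fitted):
        _, results, _ = fitted
        text = results.summary()
        for _, ps in results.model.gene_set:
            assert ps in text
        assert "log-rank" in text

    def test_deterministic_refit(self, fitted):
        est, results, _ = fitted
        again = est.fit(seed=1)
        assert again.model.to_json() == results.model.to_json()

    def test_build_requires_replicated_genes(self, fitted):
        est, _, cohorts = fitted
        null_est = CdGeneRiskScore(cohorts[0], validation=[cohorts[1]],
                                   candidates=probeset_names(50), alpha_screen=1e-30)
        with pytest.raises(BuildError):
            null_est.fit()
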