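"""The CD gene risk score: count-based staging over a frozen gene set,
log-rank-driven merging of adjacent stages, and 2-class risk evaluation.

A fitted model holds a gene set (symbol, probeset), one expression
cutpoint per gene on the training-cohort scale, and a merge map sending
each count stage (1 = no gene high ... G = all genes high) to a risk
class.  "High" expression means strictly greater than the cutpoint.

Cutpoints applied to an external cohort are, by default, re-derived on
that cohort's own expression by the maxstat procedure (``recalibrate``
mode), because absolute MAS5 intensity scales are not comparable across
platforms/cohorts; a ``frozen`` mode applies the training values as-is.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .exceptions import (
    BuildError,
    DesignError,
    ModelApplicationError,
    ValidationError,
)
from .maxstat import DEFAULT_BAND, ScreenReport, maxstat_cutpoint
from .survival import KmCurve, LogrankResult, cox_fit, km_estimate, logrank_test

logger = logging.getLogger(__name__)

LOW, HIGH = "low", "high"


@dataclass
class CdScoreModel:
    """Frozen, serializable risk-score model."""

    gene_set: list[tuple[str, str]]          # (gene symbol, probeset_id)
    cutpoints: dict[str, float]              # probeset_id -> threshold
    merge_map: dict[int, str]                # stage -> "low"/"high"
    stage_blocks: dict[int, int]             # stage -> merged block index (0-based)
    alpha_merge: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        probesets = [ps for _, ps in self.gene_set]
        if sorted(self.cutpoints) != sorted(probesets):
            raise ValidationError("cutpoints must cover exactly the gene set")
        stages = list(range(1, len(self.gene_set) + 2))
        if self.merge_map and sorted(self.merge_map) != stages:
            raise ValidationError(f"merge_map must assign every stage in {stages}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_set)

    @property
    def n_stages(self) -> int:
        return self.n_genes + 1

    @property
    def is_frozen(self) -> bool:
        return bool(self.merge_map)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "genes": [
                {"symbol": sym, "probeset": ps, "cutpoint": self.cutpoints[ps]}
                for sym, ps in self.gene_set
            ],
            "merge_map": {str(k): v for k, v in sorted(self.merge_map.items())},
            "stage_blocks": {str(k): v for k, v in sorted(self.stage_blocks.items())},
            "alpha": self.alpha_merge,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "CdScoreModel":
        if source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            gene_set=[(g["symbol"], g["probeset"]) for g in payload["genes"]],
            cutpoints={g["probeset"]: float(g["cutpoint"]) for g in payload["genes"]},
            merge_map={int(k): v for k, v in payload["merge_map"].items()},
            stage_blocks={int(k): int(v) for k, v in payload.get("stage_blocks", {}).items()},
            alpha_merge=float(payload["alpha"]),
            provenance=payload.get("provenance", {}),
        )


def assign_stage(
    cohort: Cohort,
    model: CdScoreModel,
    cutpoints: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample count of genes above cutpoint and resulting stage.

    Returns a DataFrame indexed by sample_id with columns ``n_high``,
    ``stage`` (= n_high + 1) and, when the model is frozen, ``risk``.
    """
    cuts = cutpoints or model.cutpoints
    expr = cohort.expression.values
    missing = [ps for _, ps in model.gene_set if ps not in expr.index]
    if missing:
        raise ModelApplicationError(
            f"cohort {cohort.name!r} lacks model probeset(s) {missing}"
        )
    n_high = np.zeros(cohort.n_samples, dtype=int)
    for _, ps in model.gene_set:
        n_high += (expr.loc[ps].to_numpy(dtype=float) > cuts[ps]).astype(int)
    out = pd.DataFrame(
        {"n_high": n_high, "stage": n_high + 1},
        index=pd.Index(cohort.sample_ids, name="sample_id"),
    )
    if model.is_frozen:
        out["risk"] = out["stage"].map(model.merge_map)
    return out


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _block_logrank(times, events, member_a, member_b) -> float:
    """p-value of the two-group log-rank between two blocks; blocks whose
    union carries no events are statistically indistinguishable (p=1)."""
    sel = member_a | member_b
    if events[sel].sum() == 0:
        return 1.0
    group = np.where(member_a[sel], "a", "b")
    return logrank_test(times[sel], events[sel], group).p_value


def merge_stages(
    stages,
    times,
    events,
    alpha: float = 0.05,
    n_stages: int | None = None,
) -> tuple[dict[int, str], dict[int, int], pd.DataFrame]:
    """Merge adjacent count-score stages until every adjacent pair differs.

    Scanning starts at the lowest-indexed adjacent pair; a non-significant
    pair (log-rank p >= alpha) is merged and the scan restarts from the
    bottom, a significant pair advances the scan.  Empty stages are
    absorbed into their lower neighbor (the lowest stage into its upper
    neighbor).  Final blocks are labeled low/high risk by Kaplan-Meier
    median (worse-median side = high); with more than two terminal blocks
    the binary boundary is the contiguous split maximizing the two-group
    log-rank chi-square.

    Returns ``(merge_map, stage_blocks, diagnostics)``.
    """
    stages = np.asarray(stages, dtype=int)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if stages.size == 0 or events.sum() == 0:
        raise DesignError("merge_stages needs nonempty stages with >= 1 event")
    n_stages = n_stages or int(stages.max())
    all_stages = list(range(1, n_stages + 1))
    occupied = [s for s in all_stages if (stages == s).any()]
    if len(occupied) == 0:
        raise DesignError("all stages empty")

    # initial blocks: one per occupied stage, in stage order
    blocks: list[list[int]] = [[s] for s in occupied]
    # absorb empty stages into the lower occupied neighbor (stage 1 side
    # empties attach upward)
    for s in all_stages:
        if s in occupied:
            continue
        lower = [b for b in blocks if b[-1] < s]
        target = lower[-1] if lower else blocks[0]
        target.append(s)
        target.sort()
    blocks.sort(key=lambda b: b[0])

    def members(block):
        return np.isin(stages, block)

    tests: list[dict] = []
    i = 0
    while len(blocks) > 1 and i < len(blocks) - 1:
        p = _block_logrank(times, events, members(blocks[i]), members(blocks[i + 1]))
        tests.append({"block_a": tuple(blocks[i]), "block_b": tuple(blocks[i + 1]), "p": p})
        if p >= alpha:
            blocks[i] = sorted(blocks[i] + blocks[i + 1])
            del blocks[i + 1]
            i = 0          # restart the scan from the lowest pair
        else:
            i += 1

    stage_blocks = {s: bi for bi, block in enumerate(blocks) for s in block}
    risk_by_block = _label_blocks(blocks, stages, times, events)
    merge_map = {s: risk_by_block[stage_blocks[s]] for s in all_stages}
    return merge_map, stage_blocks, pd.DataFrame(tests)


def _label_blocks(blocks, stages, times, events) -> dict[int, str]:
    """Binary low/high risk labels over ordered blocks."""
    k = len(blocks)
    if k == 1:
        logger.warning("merge collapsed to a single block; score is uninformative")
        return {0: LOW}

    def block_median(block):
        sel = np.isin(stages, block)
        curve = km_estimate(times[sel], events[sel])
        med = curve.median_survival
        # "not reached" sorts as best; tie-break on final survival prob
        tail = curve.survival_prob[-1] if curve.survival_prob.size else 1.0
        return (np.inf if med is None else med, tail)

    if k == 2:
        boundary = 1
    else:
        best_chi2, boundary = -1.0, 1
        for b in range(1, k):
            lower = [s for blk in blocks[:b] for s in blk]
            group = np.where(np.isin(stages, lower), "lower", "upper")
            try:
                chi2 = logrank_test(times, events, group).chi2
            except DesignError:
                continue
            if chi2 > best_chi2:
                best_chi2, boundary = chi2, b
    lower_stages = [s for blk in blocks[:boundary] for s in blk]
    upper_stages = [s for blk in blocks[boundary:] for s in blk]
    med_lower = block_median(lower_stages)
    med_upper = block_median(upper_stages)
    lower_risk = HIGH if med_lower < med_upper else LOW
    upper_risk = LOW if lower_risk == HIGH else HIGH
    return {
        bi: (lower_risk if bi < boundary else upper_risk) for bi in range(k)
    }


# ---------------------------------------------------------------------------
# model building & evaluation
# ---------------------------------------------------------------------------

def build_model(
    training: Cohort,
    screen: ScreenReport,
    endpoint: str = "os",
    alpha_merge: float = 0.05,
    gene_map: dict[str, str] | None = None,
    seed: int | None = None,
) -> CdScoreModel:
    """Freeze a risk-score model from a replication screen.

    Gene set = replicated probesets (probeset-ID order); cutpoints = the
    training cohort's maxstat cutpoints; merge map from the training
    cohort's stage survival.
    """
    if not screen.replicated:
        raise BuildError("screen produced no replicated prognostic gene")
    gene_map = gene_map or {}
    gene_set = [(gene_map.get(ps, ps), ps) for ps in screen.replicated]
    cutpoints = screen.training_cutpoints(training.name)
    model = CdScoreModel(
        gene_set=gene_set,
        cutpoints=cutpoints,
        merge_map={},
        stage_blocks={},
        alpha_merge=alpha_merge,
        provenance={
            "training_cohort": training.name,
            "endpoint": endpoint,
            "alpha_screen": screen.alpha,
            "band": list(screen.band),
            "seed": seed,
        },
    )
    assignment = assign_stage(training, model)
    times, events = training.survival(endpoint)
    merge_map, stage_blocks, _ = merge_stages(
        assignment["stage"].to_numpy(), times, events,
        alpha=alpha_merge, n_stages=model.n_stages,
    )
    model.merge_map = merge_map
    model.stage_blocks = stage_blocks
    return model


@dataclass
class RiskClassStats:
    risk: str
    n: int
    percent: float
    n_events: int
    median_survival: float | None
    km: KmCurve | None


@dataclass
class EvaluationReport:
    cohort_name: str
    endpoint: str
    cutpoint_mode: str
    cutpoints: dict[str, float]
    assignment: pd.DataFrame
    classes: list[RiskClassStats]
    logrank: LogrankResult | None
    hazard_ratio_high: float | None       # Cox HR of high vs low risk
    hazard_ratio_low: float | None        # inverse coding (low vs high)
    cox_p: float | None
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "risk": c.risk,
                "n": c.n,
                "percent": c.percent,
                "n_events": c.n_events,
                "median_survival": "NR" if c.median_survival is None else c.median_survival,
            }
            for c in self.classes
        ]
        return pd.DataFrame(rows)


def evaluate(
    cohort: Cohort,
    model: CdScoreModel,
    endpoint: str = "os",
    cutpoint_mode: str = "recalibrate",
    band: tuple[float, float] = DEFAULT_BAND,
) -> EvaluationReport:
    """Apply a frozen model to a cohort and summarize per-risk-class
    survival (KM, median, log-rank, Cox hazard ratio in both codings)."""
    if not model.is_frozen:
        raise ModelApplicationError("model merge_map is unset; build/freeze it first")
    if cutpoint_mode not in ("recalibrate", "frozen"):
        raise ValueError(f"cutpoint_mode must be 'recalibrate' or 'frozen'")
    times, events = cohort.survival(endpoint)
    warnings_: list[str] = []

    if cutpoint_mode == "frozen":
        cuts = dict(model.cutpoints)
    else:
        cuts = {}
        for _, ps in model.gene_set:
            if ps not in cohort.expression.values.index:
                raise ModelApplicationError(
                    f"cohort {cohort.name!r} lacks model probeset {ps!r}"
                )
            x = cohort.expression.values.loc[ps].to_numpy(dtype=float)
            cuts[ps] = maxstat_cutpoint(
                x, times, events, band=band, probeset_id=ps
            ).cutpoint

    assignment = assign_stage(cohort, model, cutpoints=cuts)
    n = len(assignment)
    classes: list[RiskClassStats] = []
    for risk in (LOW, HIGH):
        sel = (assignment["risk"] == risk).to_numpy()
        if sel.sum() == 0:
            warnings_.append(f"risk class {risk!r} empty in cohort {cohort.name!r}")
            classes.append(RiskClassStats(risk, 0, 0.0, 0, None, None))
            continue
        km = km_estimate(times[sel], events[sel])
        classes.append(
            RiskClassStats(
                risk=risk,
                n=int(sel.sum()),
                percent=100.0 * sel.sum() / n,
                n_events=int(events[sel].sum()),
                median_survival=km.median_survival,
                km=km,
            )
        )

    logrank = None
    hr_high = hr_low = cox_p = None
    if all(c.n > 0 for c in classes):
        risk_arr = assignment["risk"].to_numpy()
        try:
            logrank = logrank_test(times, events, risk_arr)
        except DesignError as exc:
            warnings_.append(str(exc))
        try:
            X = pd.DataFrame({"high_risk": (risk_arr == HIGH).astype(float)})
            fit = cox_fit(times, events, X)
            hr_high = fit.hazard_ratio("high_risk")
            hr_low = 1.0 / hr_high
            cox_p = float(fit.summary.loc["high_risk", "p"])
        except DesignError as exc:
            warnings_.append(f"Cox on risk class failed: {exc}")
    else:
        warnings_.append("between-class tests skipped (empty risk class)")
    for w in warnings_:
        logger.warning("evaluate(%s): %s", cohort.name, w)
    return EvaluationReport(
        cohort_name=cohort.name,
        endpoint=endpoint,
        cutpoint_mode=cutpoint_mode,
        cutpoints=cuts,
        assignment=assignment,
        classes=classes,
        logrank=logrank,
        hazard_ratio_high=hr_high,
        hazard_ratio_low=hr_low,
        cox_p=cox_p,
        warnings=warnings_,
    )
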