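"""End-to-end orchestration: load cohorts, differential screen, prognostic
screen, score construction, validation, Cox report.

All stochastic stages draw their seed from the single configured run seed
through ``derive_seed(seed, stage_name)`` (a CRC32 mix, kept below 2**31),
so a rerun with the same config is byte-identical.  Every sample or
probeset excluded anywhere is enumerated in the machine-readable run log.
Wall-clock information lives only in the run log, never in the model or
evaluation artifacts.
"""

from __future__ import annotations

import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort
from .exceptions import CdScoreError, ConfigurationError
from .io import (
    class_labels_from_clinical,
    load_candidates,
    load_clinical,
    load_expression,
    load_probeset_map,
)
from .cohort import align_cohort
from .model import CdGeneRiskScore
from .sam import sam, select_deregulated
from .survival import cox_report

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Stage-specific seed derived from the run seed (stable, < 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class CohortSpec:
    name: str
    expression: str
    clinical: str


@dataclass
class RunConfig:
    training: CohortSpec
    validation: list[CohortSpec] = field(default_factory=list)
    candidates: str | None = None
    gene_map: str | None = None
    endpoint: str = "os"
    fdr_percent: float = 5.0
    fold: float = 2.0
    alpha: float = 0.05
    band: tuple[float, float] = (0.10, 0.90)
    alpha_merge: float = 0.05
    n_perm: int = 1000
    seed: int = 17
    cutpoint_mode: str = "recalibrate"
    sam_class1: str = "BMPC"
    sam_class2: str = "MMC"

    def validate(self) -> None:
        if not (0 < self.fdr_percent <= 100):
            raise ConfigurationError(f"fdr_percent must be in (0, 100], got {self.fdr_percent}")
        if self.fold < 1:
            raise ConfigurationError(f"fold must be >= 1, got {self.fold}")
        for name, a in (("alpha", self.alpha), ("alpha_merge", self.alpha_merge)):
            if not (0 < a < 1):
                raise ConfigurationError(f"{name} must be in (0, 1), got {a}")
        q_lo, q_hi = self.band
        if not (0 < q_lo < q_hi < 1):
            raise ConfigurationError(f"band must satisfy 0 < lo < hi < 1, got {self.band}")
        if self.n_perm < 100:
            raise ConfigurationError(f"n_perm must be >= 100, got {self.n_perm}")
        if self.endpoint not in ("os", "efs"):
            raise ConfigurationError(f"endpoint must be os or efs, got {self.endpoint!r}")
        if self.cutpoint_mode not in ("recalibrate", "frozen"):
            raise ConfigurationError(f"bad cutpoint_mode {self.cutpoint_mode!r}")
        for spec in [self.training, *self.validation]:
            for path in (spec.expression, spec.clinical):
                if not os.path.exists(path):
                    raise ConfigurationError(f"cohort file not found: {path}")
        for path in (self.candidates, self.gene_map):
            if path is not None and not os.path.exists(path):
                raise ConfigurationError(f"file not found: {path}")

    def to_dict(self) -> dict[str, Any]:
        def spec_d(s: CohortSpec):
            return {"name": s.name, "expression": s.expression, "clinical": s.clinical}

        return {
            "training": spec_d(self.training),
            "validation": [spec_d(s) for s in self.validation],
            "candidates": self.candidates,
            "gene_map": self.gene_map,
            "endpoint": self.endpoint,
            "fdr_percent": self.fdr_percent,
            "fold": self.fold,
            "alpha": self.alpha,
            "band": list(self.band),
            "alpha_merge": self.alpha_merge,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "cutpoint_mode": self.cutpoint_mode,
            "sam_class1": self.sam_class1,
            "sam_class2": self.sam_class2,
        }

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def spec(d):
            return CohortSpec(name=d["name"], expression=d["expression"],
                              clinical=d["clinical"])

        kwargs = {k: v for k, v in raw.items()
                  if k not in ("training", "validation", "band")}
        cfg = cls(
            training=spec(raw["training"]),
            validation=[spec(d) for d in raw.get("validation", [])],
            **kwargs,
        )
        if "band" in raw:
            cfg.band = tuple(raw["band"])
        return cfg


def _load_cohort(spec: CohortSpec) -> Cohort:
    expr = load_expression(spec.expression)
    clin = load_clinical(spec.clinical)
    labels = class_labels_from_clinical(clin)
    return align_cohort(expr, clin, class_labels=labels, name=spec.name)


def _write_tsv(df: pd.DataFrame, path: str, provenance: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cdscore {__version__}\n# {provenance}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir: str) -> dict[str, Any]:
    """Execute the full pipeline, writing artifacts into ``outdir``.

    Returns the run log (also written as ``run_log.json``).  Any stage
    failure raises with the stage name in the message.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    log: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "exclusions": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except CdScoreError as exc:
                log["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_log(log, outdir)
                raise CdScoreError(f"stage {name!r} failed: {exc}") from exc
            log["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
            return out
        return deco

    @stage("load")
    def cohorts():
        out = {"training": _load_cohort(config.training)}
        for spec in config.validation:
            out[spec.name] = _load_cohort(spec)
        for name, c in out.items():
            rep = c.alignment_report
            if rep.n_dropped:
                log["exclusions"][f"{name}:alignment"] = {
                    "expression_only": rep.dropped_expression,
                    "clinical_only": rep.dropped_clinical,
                }
        return out

    training = cohorts["training"]
    validation = [c for k, c in cohorts.items() if k != "training"]
    candidates = (load_candidates(config.candidates) if config.candidates
                  else training.expression.probeset_ids)
    gene_map = load_probeset_map(config.gene_map) if config.gene_map else {}

    # differential screen (only when both classes are present)
    labels = set(training.class_labels)
    if {config.sam_class1, config.sam_class2} <= labels:
        @stage("sam")
        def sam_out():
            res = sam(training, config.sam_class1, config.sam_class2,
                      n_perm=config.n_perm, seed=derive_seed(config.seed, "sam"))
            up, down = select_deregulated(res, config.fdr_percent, config.fold)
            tab = res.table.copy()
            tab["call"] = "ns"
            tab.loc[tab.index.isin(up), "call"] = "up"
            tab.loc[tab.index.isin(down), "call"] = "down"
            if gene_map:
                tab.insert(0, "gene", [gene_map.get(p, "") for p in tab.index])
            _write_tsv(tab, os.path.join(outdir, "sam_results.tsv"),
                       f"sam {config.sam_class1} vs {config.sam_class2}; "
                       f"n_perm={config.n_perm}; s0={res.s0:.6g}; "
                       f"seed={derive_seed(config.seed, 'sam')}")
            return {"up": up, "down": down, "s0": res.s0}
        log["stages"]["sam"]["n_up"] = len(sam_out["up"])
        log["stages"]["sam"]["n_down"] = len(sam_out["down"])
    else:
        logger.warning("skipping SAM stage: classes %r/%r not both present",
                       config.sam_class1, config.sam_class2)
        log["stages"]["sam"] = {"status": "skipped",
                                "reason": "class labels absent"}

    @stage("screen_and_build")
    def results():
        est = CdGeneRiskScore(
            training,
            validation=validation,
            candidates=candidates,
            gene_map=gene_map,
            endpoint=config.endpoint,
            alpha_screen=config.alpha,
            band=config.band,
            alpha_merge=config.alpha_merge,
        )
        return est.fit(seed=config.seed)

    for name, tab in results.screen.per_cohort.items():
        _write_tsv(tab, os.path.join(outdir, f"screen_{name}.tsv"),
                   f"maxstat screen; cohort={name}; endpoint={config.endpoint}; "
                   f"band={config.band}; alpha={config.alpha}")
    for name, miss in results.screen.missing.items():
        if miss:
            log["exclusions"][f"{name}:screen"] = miss
    log["stages"]["screen_and_build"]["replicated"] = results.screen.replicated
    results.model.to_json(os.path.join(outdir, "model.json"))

    @stage("evaluate")
    def evals():
        out = {}
        for cohort in [training, *validation]:
            mode = "frozen" if cohort is training else config.cutpoint_mode
            rep = results.evaluate(cohort, cutpoint_mode=mode)
            out[cohort.name] = rep
            frame = rep.to_frame()
            if rep.logrank is not None:
                frame["logrank_chi2"] = rep.logrank.chi2
                frame["logrank_p"] = rep.logrank.p_value
            if rep.hazard_ratio_high is not None:
                frame["cox_hr_high_vs_low"] = rep.hazard_ratio_high
                frame["cox_p"] = rep.cox_p
            _write_tsv(frame, os.path.join(outdir, f"eval_{cohort.name}.tsv"),
                       f"risk-score evaluation; cohort={cohort.name}; "
                       f"endpoint={config.endpoint}; cutpoint_mode={mode}",
                       index=False)
        return out

    @stage("cox_report")
    def cox_tables():
        covs = training.clinical.covariate_names
        frame = results.training_evaluation.assignment
        clin = training.clinical.table.copy()
        clin["cd_risk_high"] = (frame["risk"] == "high").astype(float)
        tables = []
        for design in ("univariate", "pairwise", "full"):
            tab = cox_report(clin, ["cd_risk_high", *covs], endpoint=config.endpoint,
                             design=design, primary="cd_risk_high")
            tables.append(tab)
        full = pd.concat(tables, ignore_index=True)
        _write_tsv(full, os.path.join(outdir, "cox_report.tsv"),
                   f"Cox analyses; training={training.name}; "
                   f"endpoint={config.endpoint}", index=False)
        return full

    _ = evals, cox_tables
    _write_log(log, outdir)
    return log


def _write_log(log: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
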