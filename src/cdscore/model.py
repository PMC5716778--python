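"""Model/Results facade over the risk-score pipeline.

``CdGeneRiskScore`` is constructed from a training cohort (plus optional
validation cohorts and a candidate probeset list); ``fit()`` runs the
cross-cohort maxstat replication screen, freezes the count-score model on
the training cohort and returns a ``CdGeneRiskScoreResults`` carrying the
frozen model, the screening tables, per-cohort evaluations and a
``summary()`` table.
"""

from __future__ import annotations

import logging

import pandas as pd

from .cohort import Cohort
from .maxstat import DEFAULT_BAND, ScreenReport, screen_prognostic
from .score import CdScoreModel, EvaluationReport, build_model, evaluate

logger = logging.getLogger(__name__)


class CdGeneRiskScore:
    """Count-based CD-gene risk score model.

    Parameters
    ----------
    training
        Cohort on which cutpoints and the stage merge are learned.
    validation
        Additional cohorts entering the replication filter (a gene must be
        prognostic, same direction, in every cohort to be retained).
    candidates
        Probeset IDs to screen; defaults to every probeset of the
        training cohort.
    gene_map
        Optional probeset -> gene-symbol map for reporting.
    """

    def __init__(
        self,
        training: Cohort,
        validation: list[Cohort] | tuple = (),
        candidates: list[str] | None = None,
        gene_map: dict[str, str] | None = None,
        endpoint: str = "os",
        alpha_screen: float = 0.05,
        band: tuple[float, float] = DEFAULT_BAND,
        alpha_merge: float = 0.05,
    ):
        self.training = training
        self.validation = list(validation)
        self.candidates = candidates or training.expression.probeset_ids
        self.gene_map = gene_map or {}
        self.endpoint = endpoint
        self.alpha_screen = alpha_screen
        self.band = band
        self.alpha_merge = alpha_merge

    def fit(self, seed: int | None = None) -> "CdGeneRiskScoreResults":
        cohorts = [self.training, *self.validation]
        screen = screen_prognostic(
            cohorts,
            self.candidates,
            endpoint=self.endpoint,
            alpha=self.alpha_screen,
            band=self.band,
        )
        model = build_model(
            self.training,
            screen,
            endpoint=self.endpoint,
            alpha_merge=self.alpha_merge,
            gene_map=self.gene_map,
            seed=seed,
        )
        return CdGeneRiskScoreResults(self, model, screen)


class CdGeneRiskScoreResults:
    """Fitted risk score: frozen model + screen + evaluation helpers."""

    def __init__(self, spec: CdGeneRiskScore, model: CdScoreModel, screen: ScreenReport):
        self.model_spec = spec
        self.model = model
        self.screen = screen
        self._training_eval: EvaluationReport | None = None

    @property
    def gene_set(self) -> list[tuple[str, str]]:
        return self.model.gene_set

    @property
    def merge_map(self) -> dict[int, str]:
        return self.model.merge_map

    @property
    def training_evaluation(self) -> EvaluationReport:
        if self._training_eval is None:
            # frozen cutpoints on the training cohort: self-application is
            # exact by construction
            self._training_eval = evaluate(
                self.model_spec.training, self.model,
                endpoint=self.model_spec.endpoint, cutpoint_mode="frozen",
            )
        return self._training_eval

    def predict(self, cohort: Cohort, cutpoint_mode: str = "recalibrate") -> pd.DataFrame:
        """Stage and risk-class assignment for each sample of ``cohort``."""
        rep = self.evaluate(cohort, cutpoint_mode=cutpoint_mode)
        return rep.assignment

    def evaluate(
        self,
        cohort: Cohort,
        endpoint: str | None = None,
        cutpoint_mode: str = "recalibrate",
    ) -> EvaluationReport:
        return evaluate(
            cohort,
            self.model,
            endpoint=endpoint or self.model_spec.endpoint,
            cutpoint_mode=cutpoint_mode,
            band=self.model_spec.band,
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = ["CD gene risk score", "=" * 60]
        lines.append(f"training cohort : {self.model_spec.training.name}"
                     f" (n={self.model_spec.training.n_samples})")
        for c in self.model_spec.validation:
            lines.append(f"validation      : {c.name} (n={c.n_samples})")
        lines.append(f"endpoint        : {self.model_spec.endpoint}")
        lines.append(f"candidates      : {len(self.model_spec.candidates)} probesets")
        lines.append(f"replicated genes: {len(self.screen.replicated)}")
        lines.append("")
        lines.append(f"{'gene':<12}{'probeset':<16}{'cutpoint':>12}{'direction':>12}")
        train_tab = self.screen.per_cohort[self.model_spec.training.name]
        for sym, ps in self.model.gene_set:
            direction = train_tab.loc[ps, "direction"] if ps in train_tab.index else "?"
            lines.append(
                f"{sym:<12}{ps:<16}{self.model.cutpoints[ps]:>12.4g}{direction:>12}"
            )
        lines.append("")
        lines.append("stage -> risk: " + ", ".join(
            f"{s}:{r}" for s, r in sorted(self.model.merge_map.items())
        ))
        ev = self.training_evaluation
        lines.append("")
        lines.append(f"{'risk':<8}{'n':>6}{'%':>8}{'events':>8}{'median OS':>12}")
        for c in ev.classes:
            med = "NR" if c.median_survival is None else f"{c.median_survival:.1f}"
            lines.append(f"{c.risk:<8}{c.n:>6}{c.percent:>8.1f}{c.n_events:>8}{med:>12}")
        if ev.logrank is not None:
            lines.append(
                f"log-rank chi2={ev.logrank.chi2:.3f}, p={ev.logrank.p_value:.3g}"
            )
        if ev.hazard_ratio_high is not None:
            lines.append(
                f"Cox HR (high vs low)={ev.hazard_ratio_high:.3f}; "
                f"(low vs high)={ev.hazard_ratio_low:.3f}; p={ev.cox_p:.3g}"
            )
        return "\n".join(lines)

    def plot_km(self, cohort: Cohort | None = None, cutpoint_mode: str = "recalibrate",
                ax=None):
        """Kaplan-Meier curves per risk class (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        rep = (self.training_evaluation if cohort is None
               else self.evaluate(cohort, cutpoint_mode=cutpoint_mode))
        if ax is None:
            _, ax = plt.subplots()
        colors = {"low": "tab:green", "high": "tab:red"}
        for c in rep.classes:
            if c.km is None:
                continue
            t = [0.0, *c.km.event_times]
            s = [1.0, *c.km.survival_prob]
            ax.step(t, s, where="post", label=f"{c.risk} risk (n={c.n})",
                    color=colors.get(c.risk))
        ax.set_xlabel(f"{rep.endpoint.upper()} time (months)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        if rep.logrank is not None:
            ax.set_title(f"{rep.cohort_name}: log-rank p={rep.logrank.p_value:.2g}")
        return ax
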