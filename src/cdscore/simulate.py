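"""Synthetic cohorts with known ground truth.

Expression marginals are log-normal on the linear scale (log2-normal with
configurable sigma), mimicking the positive, heavy-tailed shape of
MAS5-normalized intensities.  Two generators cover the two study designs:

* a two-class (BMPC vs MMC) design with planted linear fold changes for
  the differential screen, and
* a survival design where each patient's hazard follows a proportional-
  hazards model on *dichotomized* planted genes,
  ``h_i = h0 * exp(sum_g beta_g * 1[x_gi > c_g])`` with ``c_g`` the
  q*-quantile of gene g's expression, exponential event times, and
  independent uniform censoring whose horizon is calibrated by bisection
  so the realized censoring fraction hits the target.

A continuous-effect variant (hazard linear in log2 expression z-score) is
available for robustness checks, and a staged generator plants a known
block structure on the 5-stage count score for merge testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ClinicalTable, Cohort, ExpressionMatrix
from .exceptions import ConfigurationError

#: defaults emulating a myeloma microarray cohort: month-scale baseline
#: hazard (median untreated-group OS around 46 months) and the censoring
#: typical of the published cohorts.
DEFAULT_BASELINE_HAZARD = 0.015
DEFAULT_CENSOR_RATE = 0.25
DEFAULT_SIGMA_LOG2 = 0.5


@dataclass
class PlantedGene:
    """Ground truth for one prognostic gene."""

    cut_quantile: float           # q* in (0,1): cutpoint at this expression quantile
    beta: float                   # log-hazard effect of being above the cutpoint

    def __post_init__(self):
        if not 0 < self.cut_quantile < 1:
            raise ConfigurationError(
                f"cut_quantile must be in (0,1), got {self.cut_quantile}"
            )


@dataclass
class SyntheticTruth:
    """Planted structure shared by the generators."""

    planted_de: dict[str, float] = field(default_factory=dict)
    planted_prognostic: dict[str, PlantedGene] = field(default_factory=dict)
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD
    censor_rate: float = DEFAULT_CENSOR_RATE
    sigma_log2: float = DEFAULT_SIGMA_LOG2
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.censor_rate < 1:
            raise ConfigurationError(
                f"censor_rate must be in [0,1), got {self.censor_rate}"
            )
        for ps, fold in self.planted_de.items():
            if fold <= 0:
                raise ConfigurationError(f"fold change for {ps} must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")


def probeset_names(n: int) -> list[str]:
    return [f"ps{i:05d}_at" for i in range(n)]


def _base_expression(rng, n_probesets: int, n_samples: int, sigma: float):
    """Log2-scale baseline: per-probeset mean uniform on [5, 11]."""
    mu = rng.uniform(5.0, 11.0, size=n_probesets)
    return mu[:, None] + sigma * rng.standard_normal((n_probesets, n_samples))


def _resolve_probesets(truth_keys, n_probesets: int) -> list[str]:
    names = probeset_names(n_probesets)
    extra = [k for k in truth_keys if k not in set(names)]
    if extra:
        raise ConfigurationError(
            f"planted probesets {extra[:5]} outside the {n_probesets}-probeset grid; "
            f"use names from probeset_names(n)"
        )
    return names


def generate_two_class(
    n_bmpc: int,
    n_mmc: int,
    n_probesets: int,
    truth: SyntheticTruth,
) -> Cohort:
    """Two-class cohort with planted linear fold changes (MMC over BMPC).

    Planted probesets shift the MMC log2 mean by log2(fold), so the ratio
    of arithmetic class means equals the fold change in expectation.
    """
    if n_bmpc < 2 or n_mmc < 2:
        raise ConfigurationError("need >= 2 samples per class")
    if len(truth.planted_de) > n_probesets:
        raise ConfigurationError(
            f"{len(truth.planted_de)} planted DE probesets exceed "
            f"n_probesets={n_probesets}"
        )
    names = _resolve_probesets(truth.planted_de, n_probesets)
    rng = np.random.default_rng(truth.seed)
    n = n_bmpc + n_mmc
    log2x = _base_expression(rng, n_probesets, n, truth.sigma_log2)
    idx = {ps: i for i, ps in enumerate(names)}
    for ps, fold in truth.planted_de.items():
        log2x[idx[ps], n_bmpc:] += np.log2(fold)
    samples = [f"S{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(2.0**log2x, probeset_ids=names, sample_ids=samples)
    # survival annotations are baseline-only here (the design is the
    # two-class contrast); kept so the container is a full Cohort
    times = rng.exponential(1.0 / truth.baseline_hazard, size=n)
    clin = ClinicalTable(pd.DataFrame({
        "sample_id": samples,
        "os_time": np.round(times, 6),
        "os_event": np.ones(n, dtype=int),
    }))
    labels = pd.Series(["BMPC"] * n_bmpc + ["MMC"] * n_mmc, index=samples)
    cohort = Cohort(expr, clin, class_labels=labels, name="synthetic_two_class")
    cohort.truth = truth
    return cohort


def _calibrate_censoring(T: np.ndarray, u: np.ndarray, target: float) -> float:
    """Bisection on the censoring horizon H (C_i = H * u_i) so the realized
    censored fraction is as close to ``target`` as the sample allows."""
    def frac_censored(H):
        return float(np.mean(T > H * u))

    lo, hi = 1e-9, float(T.max() / max(u.min(), 1e-12)) * 2 + 1.0
    if frac_censored(hi) > target:  # pragma: no cover - u floor keeps this rare
        raise ConfigurationError("target censor_rate unattainable with finite horizon")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac_censored(mid) > target:
            lo = mid
        else:
            hi = mid
    return hi


def generate_survival_cohort(
    n_patients: int,
    n_probesets: int,
    truth: SyntheticTruth,
    continuous_effect: bool = False,
    name: str = "synthetic_survival",
) -> tuple[Cohort, dict]:
    """Survival cohort with planted prognostic genes.

    Returns ``(cohort, resolved)`` where ``resolved`` holds the realized
    planted cutpoint values, the censoring horizon and the realized
    censoring fraction.
    """
    if n_patients < 20:
        raise ConfigurationError(f"n_patients must be >= 20, got {n_patients}")
    if len(truth.planted_prognostic) > n_probesets:
        raise ConfigurationError("more planted prognostic genes than probesets")
    names = _resolve_probesets(truth.planted_prognostic, n_probesets)
    rng = np.random.default_rng(truth.seed)
    log2x = _base_expression(rng, n_probesets, n_patients, truth.sigma_log2)
    X = 2.0**log2x
    idx = {ps: i for i, ps in enumerate(names)}

    log_hr = np.zeros(n_patients)
    cutpoints: dict[str, float] = {}
    dichotomies: dict[str, np.ndarray] = {}
    for ps, gene in truth.planted_prognostic.items():
        x = X[idx[ps]]
        if continuous_effect:
            z = (log2x[idx[ps]] - log2x[idx[ps]].mean()) / truth.sigma_log2
            log_hr += gene.beta * z
            cutpoints[ps] = float(np.quantile(x, gene.cut_quantile))
        else:
            c = float(np.quantile(x, gene.cut_quantile))
            z = x > c
            log_hr += gene.beta * z
            cutpoints[ps] = c
            dichotomies[ps] = z

    hazard = truth.baseline_hazard * np.exp(log_hr)
    T = rng.exponential(1.0 / hazard)
    if truth.censor_rate == 0:
        times, events = T, np.ones(n_patients, dtype=int)
        horizon = np.inf
    else:
        u = rng.uniform(1e-9, 1.0, size=n_patients)
        horizon = _calibrate_censoring(T, u, truth.censor_rate)
        C = horizon * u
        events = (T <= C).astype(int)
        times = np.minimum(T, C)

    samples = [f"P{i:04d}" for i in range(n_patients)]
    expr = ExpressionMatrix(X, probeset_ids=names, sample_ids=samples)
    clin = ClinicalTable(pd.DataFrame({
        "sample_id": samples,
        "os_time": times,
        "os_event": events,
    }))
    labels = pd.Series("MMC", index=samples)
    cohort = Cohort(expr, clin, class_labels=labels, name=name)
    cohort.truth = truth
    resolved = {
        "cutpoints": cutpoints,
        "dichotomies": dichotomies,
        "horizon": horizon,
        "realized_censoring": float(1 - events.mean()),
        "event_times_latent": T,
    }
    return cohort, resolved


def generate_staged_survival(
    n_patients: int,
    stage_hazards: list[float],
    stage_probs: list[float] | None = None,
    censor_rate: float = DEFAULT_CENSOR_RATE,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Survival data with a planted hazard per count-score stage.

    Stage occupancy follows ``stage_probs`` (default: binomial counts of
    4 independent fair high/low genes, i.e. the 5-stage profile of a
    4-gene score with median cutpoints).  Returns ``(stages, times,
    events)`` with stages in 1..len(stage_hazards).
    """
    k = len(stage_hazards)
    if stage_probs is None:
        if k != 5:
            raise ConfigurationError("default stage_probs assumes 5 stages")
        stage_probs = [1 / 16, 4 / 16, 6 / 16, 4 / 16, 1 / 16]
    if len(stage_probs) != k or not np.isclose(sum(stage_probs), 1.0):
        raise ConfigurationError("stage_probs must sum to 1 and match stage_hazards")
    rng = np.random.default_rng(seed)
    stages = rng.choice(np.arange(1, k + 1), size=n_patients, p=stage_probs)
    hazard = np.asarray(stage_hazards, dtype=float)[stages - 1]
    T = rng.exponential(1.0 / hazard)
    if censor_rate == 0:
        return stages, T, np.ones(n_patients, dtype=int)
    u = rng.uniform(1e-9, 1.0, size=n_patients)
    H = _calibrate_censoring(T, u, censor_rate)
    C = H * u
    return stages, np.minimum(T, C), (T <= C).astype(int)
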