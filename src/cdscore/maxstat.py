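"""Maximally selected log-rank statistics for survival cutpoint screening.

For each probeset the screen dichotomizes patients at every admissible
expression value ("high" = strictly above the cutpoint), computes the
standardized two-group log-rank statistic for each split, and reports the
cutpoint attaining the maximal absolute statistic M.  Because the cutpoint
is selected to maximize the statistic, the naive chi-square p-value is
anti-conservative; the default p-value is the improved Bonferroni bound of
Lausen & Schumacher for the supremum of the standardized log-rank process
over a proportion band, with a permutation alternative for verification.

Screening across cohorts applies Benjamini-Hochberg correction within each
cohort across the candidate list and intersects the significant,
direction-consistent probesets ("replicated" genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort
from .exceptions import DegenerateInputError, DesignError, ValidationError
from .survival import _check_surv

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.10, 0.90)

HIGH_GOOD = "high_good"
HIGH_BAD = "high_bad"


@dataclass
class MaxstatResult:
    probeset_id: str
    cutpoint: float                # expression value; "high" means x > cutpoint
    cut_quantile: float            # fraction of samples at or below the cutpoint
    M: float                       # maximal |standardized log-rank statistic|
    direction: str                 # HIGH_GOOD or HIGH_BAD
    M_ne: float = 0.0              # skewness-corrected normal-equivalent supremum
    p_approx: float | None = None
    p_bh: float | None = None
    n: int = 0
    n_events: int = 0


@dataclass
class ScreenReport:
    """Per-cohort screening tables plus the cross-cohort replicated set."""

    per_cohort: dict[str, pd.DataFrame]
    replicated: list[str]
    directions: dict[str, str]
    missing: dict[str, list[str]]
    alpha: float
    band: tuple[float, float]
    endpoint: str

    def cohort_table(self, name: str) -> pd.DataFrame:
        return self.per_cohort[name]

    def training_cutpoints(self, cohort_name: str) -> dict[str, float]:
        tab = self.per_cohort[cohort_name]
        return {p: float(tab.loc[p, "cutpoint"]) for p in self.replicated}


class SurvivalIndex:
    """Precomputed risk-set structure shared by every probeset of a cohort.

    Holds the at-risk and event-at-time indicator matrices over the
    distinct event times, so each probeset only costs two column
    reorderings and cumulative sums.
    """

    def __init__(self, times, events):
        times, events = _check_surv(times, events)
        self.times = times
        self.events = events
        self.n = times.size
        self.ev_times = np.unique(times[events == 1])
        R = times[None, :] >= self.ev_times[:, None]
        D = (events == 1)[None, :] & (times[None, :] == self.ev_times[:, None])
        self.R = R.astype(float)
        self.D = D.astype(float)
        self.n_j = self.R.sum(axis=1)
        self.d_j = self.D.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.tie_w = np.where(
                self.n_j > 1, self.d_j * (self.n_j - self.d_j) / (self.n_j - 1), 0.0
            )
        # log-rank scores a_i = delta_i - NelsonAalen(t_i): the split
        # statistic U is exactly the sum of the high group's scores, so its
        # exact permutation moments (variance, third moment) over random
        # k-subsets are available in closed form
        hazard_steps = np.where(self.n_j > 0, self.d_j / self.n_j, 0.0)
        cum_haz = np.concatenate([[0.0], np.cumsum(hazard_steps)])
        pos = np.searchsorted(self.ev_times, times, side="right")
        self.scores = events - cum_haz[pos]
        self.score_m2 = float(np.mean(self.scores**2))
        self.score_m3 = float(np.mean(self.scores**3))


def maxstat_cutpoint(
    expr_vector,
    times,
    events,
    band: tuple[float, float] = DEFAULT_BAND,
    index: SurvivalIndex | None = None,
    probeset_id: str = "",
) -> MaxstatResult:
    """Optimal survival cutpoint for one expression vector.

    Candidate cutpoints are the distinct observed expression values whose
    induced above-cutpoint group proportion lies within ``band``; ties at
    the cutpoint fall in the low group.  Among cutpoints attaining the
    maximal statistic the smallest expression value is reported.
    """
    x = np.asarray(expr_vector, dtype=float)
    q_lo, q_hi = band
    if not (0 < q_lo < q_hi < 1):
        raise ValidationError(f"band must satisfy 0 < q_lo < q_hi < 1, got {band}")
    if index is None:
        index = SurvivalIndex(times, events)
    n = index.n
    if x.size != n:
        raise ValidationError("expression vector length does not match survival input")
    if n < 20:
        raise DesignError(f"maxstat requires >= 20 subjects, got {n}")
    if index.events.sum() < 5:
        raise DesignError(f"maxstat requires >= 5 events, got {int(index.events.sum())}")
    if np.unique(x).size <= 1:
        raise DegenerateInputError(
            f"expression constant{f' for {probeset_id}' if probeset_id else ''}"
        )

    order = np.argsort(-x, kind="stable")       # descending expression
    xs = x[order]
    # distinct-value boundaries: cut value xs[k] puts the k patients with
    # x > xs[k] in the high group (strictly greater; ties go low)
    distinct_next = np.flatnonzero(xs[:-1] > xs[1:]) + 1   # k = #high candidates
    ks = distinct_next[(distinct_next >= q_lo * n) & (distinct_next <= q_hi * n)]
    if ks.size == 0:
        raise DegenerateInputError(
            "no candidate cutpoint inside the search band"
            f"{f' for {probeset_id}' if probeset_id else ''}"
        )

    csR = np.cumsum(index.R[:, order], axis=1)
    csD = np.cumsum(index.D[:, order], axis=1)
    n_high = csR[:, ks - 1]                      # (J, C)
    o_high = csD[:, ks - 1]
    p_high = n_high / index.n_j[:, None]
    U = (o_high - index.d_j[:, None] * p_high).sum(axis=0)
    V = (index.tie_w[:, None] * p_high * (1.0 - p_high)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(V > 0, U / np.sqrt(V), 0.0)

    absZ = np.abs(Z)
    M = float(absZ.max())
    best = np.flatnonzero(absZ == absZ.max())
    # smallest cutpoint value = largest high-group (largest k)
    c = best[-1]
    k = int(ks[c])
    cutpoint = float(xs[k])                      # largest value NOT in the high group
    direction = HIGH_GOOD if U[c] < 0 else HIGH_BAD

    # normal-equivalent supremum for the p-value: standardize each split's
    # score sum with its exact permutation variance and remove its exact
    # skewness by a first-order Cornish-Fisher map; the supremum bound is
    # then evaluated on near-normal marginals (the reported M above keeps
    # the conventional hypergeometric standardization)
    kk = ks.astype(float)
    V_exact = kk * (n - kk) / (n - 1) * index.score_m2
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(
            V_exact > 0,
            (kk * (n - kk) * (n - 2 * kk) / ((n - 1) * (n - 2)))
            * index.score_m3 / np.maximum(V_exact, 1e-300) ** 1.5,
            0.0,
        )
        z_exact = np.where(V_exact > 0, U / np.sqrt(V_exact), 0.0)
    z_ne = z_exact - gamma * (z_exact**2 - 1.0) / 6.0
    M_ne = float(np.abs(z_ne).max())

    return MaxstatResult(
        probeset_id=probeset_id,
        cutpoint=cutpoint,
        cut_quantile=float((n - k) / n),
        M=M,
        M_ne=M_ne,
        direction=direction,
        n=n,
        n_events=int(index.events.sum()),
    )


def maxstat_pvalue(
    M: float,
    band: tuple[float, float] = DEFAULT_BAND,
    method: str = "improved_bonferroni",
    expr_vector=None,
    times=None,
    events=None,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Approximate p-value for a maximally selected log-rank statistic.

    ``improved_bonferroni`` evaluates the Lausen-Schumacher bound for the
    supremum of the standardized log-rank process over the proportion band
    (normal ordinate times a band-dependent log term, plus the 4*phi(b)/b
    tail term), capped at 1.  ``permutation`` permutes expression against
    survival and returns the add-one exceedance fraction.
    """
    q_lo, q_hi = band
    if not (0 < q_lo < q_hi < 1):
        raise ValidationError(f"degenerate band {band}")
    if M < 0:
        raise ValidationError("M must be >= 0")
    if method == "improved_bonferroni":
        if M == 0:
            return 1.0
        b = float(M)
        log_term = np.log((q_hi * (1 - q_lo)) / (q_lo * (1 - q_hi)))
        phi = stats.norm.pdf(b)
        p = phi * (b - 1.0 / b) * log_term + 4.0 * phi / b
        return float(min(1.0, max(p, 0.0)))
    if method == "permutation":
        if expr_vector is None or times is None or events is None:
            raise ValueError("permutation method needs expr_vector, times, events")
        rng = np.random.default_rng(seed)
        x = np.asarray(expr_vector, dtype=float)
        index = SurvivalIndex(times, events)
        exceed = 0
        for _ in range(n_perm):
            xp = rng.permutation(x)
            res = maxstat_cutpoint(xp, times, events, band=band, index=index)
            if res.M >= M:
                exceed += 1
        return (1.0 + exceed) / (1.0 + n_perm)
    raise ValueError(f"unknown p-value method {method!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_cohort(
    cohort: Cohort,
    candidates: list[str],
    endpoint: str = "os",
    band: tuple[float, float] = DEFAULT_BAND,
) -> tuple[pd.DataFrame, list[str]]:
    """Maxstat + improved-Bonferroni p + BH over the candidate list for one
    cohort.  Returns (table indexed by probeset, missing-or-degenerate ids)."""
    times, events = cohort.survival(endpoint)
    index = SurvivalIndex(times, events)
    rows: list[MaxstatResult] = []
    missing: list[str] = []
    present = set(cohort.expression.values.index)
    for ps in candidates:
        if ps not in present:
            missing.append(ps)
            continue
        x = cohort.expression.values.loc[ps].to_numpy(dtype=float)
        try:
            res = maxstat_cutpoint(x, times, events, band=band, index=index,
                                   probeset_id=ps)
        except DegenerateInputError as exc:
            logger.warning("screen(%s): %s", cohort.name, exc)
            missing.append(ps)
            continue
        res.p_approx = maxstat_pvalue(res.M_ne, band=band)
        rows.append(res)
    if not rows:
        raise DesignError(f"no screenable candidate probeset in cohort {cohort.name!r}")
    tab = pd.DataFrame(
        {
            "cutpoint": [r.cutpoint for r in rows],
            "cut_quantile": [r.cut_quantile for r in rows],
            "M": [r.M for r in rows],
            "p_approx": [r.p_approx for r in rows],
            "direction": [r.direction for r in rows],
        },
        index=pd.Index([r.probeset_id for r in rows], name="probeset_id"),
    )
    tab["p_bh"] = bh_adjust(tab["p_approx"].to_numpy())
    return tab, missing


def screen_prognostic(
    cohorts: list[Cohort],
    candidates: list[str],
    endpoint: str = "os",
    alpha: float = 0.05,
    band: tuple[float, float] = DEFAULT_BAND,
) -> ScreenReport:
    """Cross-cohort replication screen.

    A candidate replicates when its BH-adjusted maxstat p-value is below
    ``alpha`` in *every* cohort with a consistent direction of effect.
    Probesets missing (or degenerate) in any cohort are reported and
    excluded from the replicated set.  A single cohort degenerates to that
    cohort's significant set (with a warning).
    """
    if not cohorts:
        raise DesignError("screen_prognostic needs at least one cohort")
    if not candidates:
        raise DesignError("empty candidate list")
    if len(cohorts) == 1:
        logger.warning(
            "screen_prognostic: single cohort %r supplied; no replication filter",
            cohorts[0].name,
        )
    per_cohort: dict[str, pd.DataFrame] = {}
    missing: dict[str, list[str]] = {}
    for cohort in cohorts:
        tab, miss = screen_cohort(cohort, candidates, endpoint=endpoint, band=band)
        per_cohort[cohort.name] = tab
        missing[cohort.name] = miss

    replicated: list[str] = []
    directions: dict[str, str] = {}
    for ps in candidates:
        ok = True
        dirs = set()
        for name, tab in per_cohort.items():
            if ps not in tab.index or not (tab.loc[ps, "p_bh"] < alpha):
                ok = False
                break
            dirs.add(tab.loc[ps, "direction"])
        if ok and len(dirs) == 1:
            replicated.append(ps)
            directions[ps] = dirs.pop()
    return ScreenReport(
        per_cohort=per_cohort,
        replicated=sorted(replicated),
        directions=directions,
        missing=missing,
        alpha=alpha,
        band=band,
        endpoint=endpoint,
    )
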