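"""Survival machinery: Kaplan-Meier curves, k-sample log-rank tests and
Cox proportional-hazards reporting.

Kaplan-Meier estimation is delegated to lifelines and Cox fitting to
statsmodels' PHReg (Efron or Breslow tie handling); the log-rank test is
implemented here directly because the cutpoint screen and the stage-merge
procedure need its internals (per-group observed/expected event counts and
the signed standardized statistic), and it is cross-checked against
lifelines in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .exceptions import DesignError, ValidationError

logger = logging.getLogger(__name__)

NOT_REACHED = "NR"


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValidationError("empty survival input")
    if times.shape != events.shape:
        raise ValidationError("times and events must have equal length")
    if not np.isfinite(times).all() or (times < 0).any():
        raise ValidationError("survival times must be finite and >= 0")
    if not np.isin(events, [0, 1]).all():
        raise ValidationError("event indicators must be 0 or 1")
    return times, events.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KmCurve:
    """Product-limit estimate evaluated at the distinct event times.

    ``survival_prob[j]`` is S(t) just after ``event_times[j]``;
    ``at_risk[j]`` counts subjects at risk just before it.  The median is
    the earliest event time with S(t) <= 0.5, or ``None`` ("not reached")
    if the curve never drops that far.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median_survival: float | None
    n: int
    total_events: int

    @property
    def median_label(self) -> str:
        return NOT_REACHED if self.median_survival is None else f"{self.median_survival:g}"

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time ``t``."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator (ties reduce the risk set
    simultaneously)."""
    times, events = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    ev = table.index[table["observed"] > 0].to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(ev).to_numpy(dtype=float)
    at_risk = table.loc[ev, "at_risk"].to_numpy(dtype=int)
    n_ev = table.loc[ev, "observed"].to_numpy(dtype=int)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KmCurve(
        event_times=ev,
        survival_prob=surv,
        at_risk=at_risk,
        n_events=n_ev,
        median_survival=median,
        n=int(times.size),
        total_events=int(events.sum()),
    )


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    chi2: float
    df: int
    p_value: float
    groups: list
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(times, events, group) -> LogrankResult:
    """k-sample log-rank test with hypergeometric variance at tied event
    times; p from chi-square with k-1 degrees of freedom."""
    times, events = _check_surv(times, events)
    group = np.asarray(group)
    if group.shape != times.shape:
        raise ValidationError("group labels must match times in length")
    levels, g = np.unique(group, return_inverse=True)
    k = levels.size
    if k < 2:
        raise DesignError(f"log-rank requires >= 2 groups, got {k}")
    if events.sum() == 0:
        raise DesignError("log-rank requires at least one event")

    onehot = np.zeros((times.size, k))
    onehot[np.arange(times.size), g] = 1.0

    ev_times = np.unique(times[events == 1])
    R = times[None, :] >= ev_times[:, None]              # (J, n) at-risk
    D = (events == 1)[None, :] & (times[None, :] == ev_times[:, None])
    n_gj = R.astype(float) @ onehot                      # (J, k)
    d_gj = D.astype(float) @ onehot
    n_j = n_gj.sum(axis=1)
    d_j = d_gj.sum(axis=1)

    E = d_j[:, None] * n_gj / n_j[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        tie_factor = np.where(n_j > 1, (n_j - d_j) / (n_j - 1), 0.0)
    p_gj = n_gj / n_j[:, None]
    w = d_j * tie_factor                                  # (J,)
    # covariance of (O-E): V_gh = sum_j w_j (delta_gh p_gj - p_gj p_hj)
    V = np.einsum("j,jg,jh->gh", w, p_gj, p_gj) * -1.0
    V[np.diag_indices(k)] += w @ p_gj

    O = d_gj.sum(axis=0)
    U = O - E.sum(axis=0)
    Vr = V[: k - 1, : k - 1]
    Ur = U[: k - 1]
    try:
        chi2 = float(Ur @ np.linalg.solve(Vr, Ur))
    except np.linalg.LinAlgError:
        chi2 = float(Ur @ np.linalg.pinv(Vr) @ Ur)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return LogrankResult(
        chi2=chi2,
        df=k - 1,
        p_value=p,
        groups=levels.tolist(),
        observed=O,
        expected=E.sum(axis=0),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    summary: pd.DataFrame          # index covariate; hr, hr_low, hr_high, coef, se, p
    ties: str
    converged: bool
    n: int
    n_events: int
    flags: list[str] = field(default_factory=list)

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(times, events, covariates: pd.DataFrame, ties: str = "efron") -> CoxResult:
    """Fit a Cox proportional-hazards model by partial-likelihood
    maximization (statsmodels PHReg backend).

    Non-convergence and apparent separation are flagged on the result,
    never silent.
    """
    times, events = _check_surv(times, events)
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    X = pd.DataFrame(covariates).astype(float)
    if len(X) != times.size:
        raise ValidationError("covariate matrix length does not match survival input")
    if X.isna().to_numpy().any():
        raise ValidationError("covariate matrix contains missing values")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise DesignError(f"covariate {col!r} is constant")
    n_events = int(events.sum())
    if n_events < X.shape[1]:
        raise DesignError(
            f"{n_events} events for {X.shape[1]} covariates; model not identifiable"
        )

    flags: list[str] = []
    mod = PHReg(times, X.to_numpy(), status=events, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = mod.fit(maxiter=100, disp=False)
            converged = bool(getattr(res, "converged", True))
        except Exception as exc:  # numerical failure
            raise DesignError(f"Cox fit failed: {exc}") from exc
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if not np.isfinite(coef).all() or not np.isfinite(se).all():
        converged = False
        flags.append("non-finite estimates")
    # scale-aware separation heuristic: a coefficient spanning >30 log-
    # hazard units across the observed covariate range is not a finite MLE
    spans = (X.max() - X.min()).to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.abs(coef) * spans > 30):
            converged = False
            flags.append("possible separation (unbounded coefficient)")
    if not converged:
        logger.warning("Cox fit did not converge cleanly: %s", flags or "optimizer")

    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        summary = pd.DataFrame(
            {
                "hr": np.exp(coef),
                "hr_low": np.exp(coef - z * se),
                "hr_high": np.exp(coef + z * se),
                "coef": coef,
                "se": se,
                "p": 2 * stats.norm.sf(np.abs(coef) / se),
            },
            index=list(X.columns),
        )
    return CoxResult(summary=summary, ties=ties, converged=converged,
                     n=int(times.size), n_events=n_events, flags=flags)


def cox_score_test(times, events, x) -> tuple[float, float]:
    """Score (Rao) test of beta=0 for a single covariate, Breslow-style.

    With a binary covariate and no tied event times this is numerically
    identical to the two-group log-rank chi-square.
    Returns ``(chi2, p_value)``.
    """
    times, events = _check_surv(times, events)
    x = np.asarray(x, dtype=float)
    order = np.argsort(-times, kind="stable")  # descending time
    xs = x[order]
    cs1 = np.cumsum(xs)
    cs2 = np.cumsum(xs * xs)
    nrisk = np.arange(1, times.size + 1, dtype=float)
    # at-risk set for subject i (sorted desc): all with time >= t_i -> prefix
    ts = times[order]
    es = events[order]
    # index of last position with time >= t_i is the last tie of t_i
    last_ge = np.searchsorted(-ts, -ts, side="right") - 1
    mean_r = cs1[last_ge] / nrisk[last_ge]
    var_r = cs2[last_ge] / nrisk[last_ge] - mean_r**2
    mask = es == 1
    U = float(np.sum(xs[mask] - mean_r[mask]))
    V = float(np.sum(var_r[mask]))
    if V <= 0:
        raise DesignError("zero score-test variance (constant covariate?)")
    chi2 = U * U / V
    return chi2, float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Table-3 style Cox reporting
# ---------------------------------------------------------------------------

def cox_report(
    clinical: pd.DataFrame,
    covariates: list[str],
    endpoint: str = "os",
    design: str = "univariate",
    primary: str | None = None,
    ties: str = "efron",
) -> pd.DataFrame:
    """Cox analyses over named clinical columns.

    design:
      * ``univariate`` — one model per covariate;
      * ``pairwise`` — the primary covariate together with each other
        covariate in turn ("2 by 2");
      * ``full`` — all covariates jointly.

    Rows with missing values are dropped per model (complete-case), and
    requested covariates absent from the table are skipped with a logged
    warning rather than an error.
    """
    if design not in ("univariate", "pairwise", "full"):
        raise ValueError(f"unknown design {design!r}")
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    for col in (tcol, ecol):
        if col not in clinical.columns:
            raise DesignError(f"clinical table lacks {col!r}")
    present = [c for c in covariates if c in clinical.columns]
    absent = [c for c in covariates if c not in clinical.columns]
    if absent:
        logger.warning("cox_report: skipping absent covariates %s", absent)
    if not present:
        raise DesignError("no requested covariate present in the clinical table")

    if design == "univariate":
        blocks = [[c] for c in present]
    elif design == "full":
        blocks = [present]
    else:
        primary = primary or present[0]
        if primary not in present:
            raise DesignError(f"primary covariate {primary!r} not available")
        blocks = [[primary, c] for c in present if c != primary]
        if not blocks:
            blocks = [[primary]]

    rows = []
    for block in blocks:
        sub = clinical[[tcol, ecol, *block]].dropna()
        if sub.empty:
            logger.warning("cox_report: block %s has no complete cases", block)
            continue
        fit = cox_fit(sub[tcol], sub[ecol], sub[block], ties=ties)
        for cov in block:
            rows.append(
                {
                    "design": design,
                    "block": "+".join(block),
                    "covariate": cov,
                    "hr": fit.summary.loc[cov, "hr"],
                    "hr_low": fit.summary.loc[cov, "hr_low"],
                    "hr_high": fit.summary.loc[cov, "hr_high"],
                    "p": fit.summary.loc[cov, "p"],
                    "n": fit.n,
                    "n_events": fit.n_events,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)
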