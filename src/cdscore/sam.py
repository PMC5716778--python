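"""Two-class unpaired SAM-style differential expression screen.

The moderated statistic is d_i = (mean2_i - mean1_i) / (s_i + s0) with s_i
the standard two-sample pooled scatter and s0 a global fudge factor chosen
(in auto mode) to minimize the coefficient of variation of d across
windows of s, searched over the percentiles {0, 5, ..., 100} of s.
Gene-level FDR (reported in percent, matching the published tables) comes
from balanced class-label permutations: for each gene's |d| used as a
calling threshold, q is the median permutation exceedance count divided by
the observed count at that threshold, capped at 100 and monotonized in |d|.

Calling combines the FDR threshold with a linear fold-change filter
("ratio >= 2 in either direction"), i.e. the published selection rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import Cohort
from .exceptions import DesignError, ValidationError

logger = logging.getLogger(__name__)

S0_PERCENTILES = np.arange(0, 101, 5)


@dataclass
class SamResult:
    """Full result of a SAM run: per-probeset table plus run metadata."""

    table: pd.DataFrame      # index probeset_id; d, numerator, s, ratio, q_percent
    s0: float
    n_perm: int
    seed: int
    class1: str
    class2: str
    exhaustive: bool = False


def _class_matrices(cohort: Cohort, class1: str, class2: str):
    ids1 = cohort.samples_with_label(class1)
    ids2 = cohort.samples_with_label(class2)
    if len(ids1) < 2 or len(ids2) < 2:
        raise DesignError(
            f"SAM needs >= 2 samples per class; got {len(ids1)} {class1!r} "
            f"and {len(ids2)} {class2!r}"
        )
    X = cohort.expression.values[ids1 + ids2].to_numpy(dtype=float)
    return X, len(ids1), len(ids2)


def _d_components(X: np.ndarray, n1: int, n2: int):
    """Numerator (mean2-mean1) and pooled scatter s per probeset row."""
    X1, X2 = X[:, :n1], X[:, n1:]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return m2 - m1, s, m1, m2


def _auto_s0(num: np.ndarray, s: np.ndarray, n_windows: int = 10) -> float:
    """Fudge factor minimizing the coefficient of variation of the MAD of
    d across quantile windows of s (zero-scatter probesets excluded)."""
    live = s > 0
    if live.sum() < n_windows:
        return float(np.median(s[live])) if live.any() else 0.0
    s_live, num_live = s[live], num[live]
    order = np.argsort(s_live, kind="stable")
    bins = np.array_split(order, n_windows)
    best_s0, best_cv = 0.0, np.inf
    for s0 in np.percentile(s_live, S0_PERCENTILES):
        d = num_live / (s_live + s0)
        mads = np.array([np.median(np.abs(d[b] - np.median(d[b]))) for b in bins])
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std() / mean
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_statistics(
    cohort: Cohort,
    class1: str,
    class2: str,
    s0_mode: str = "auto",
    s0: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-probeset moderated statistics.

    Returns a DataFrame (index probeset_id) with columns ``d``,
    ``numerator``, ``s``, ``ratio`` (linear mean ratio class2/class1)
    plus the fudge factor used.
    """
    if s0_mode not in ("auto", "fixed"):
        raise ValueError(f"s0_mode must be 'auto' or 'fixed', got {s0_mode!r}")
    if s0_mode == "fixed":
        if s0 is None or s0 < 0:
            raise ValidationError("fixed s0_mode requires s0 >= 0")
    X, n1, n2 = _class_matrices(cohort, class1, class2)
    num, scatter, m1, m2 = _d_components(X, n1, n2)
    if s0_mode == "auto":
        s0 = _auto_s0(num, scatter)
    denom = scatter + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, num / denom, 0.0)
        ratio = np.where(m1 > 0, m2 / m1, np.inf)
    zero_scatter = (scatter == 0) & (num == 0)
    if zero_scatter.any():
        logger.warning("%d probeset(s) constant within both classes", zero_scatter.sum())
    table = pd.DataFrame(
        {"d": d, "numerator": num, "s": scatter, "ratio": ratio,
         "zero_scatter": zero_scatter},
        index=pd.Index(cohort.expression.values.index, name="probeset_id"),
    )
    return table, float(s0)


def _permutation_indicators(n: int, n1: int, n_perm: int, seed: int):
    """Columns are 0/1 indicators of class-1 membership for each balanced
    permutation; exhaustive enumeration when feasible."""
    total = math.comb(n, n1)
    if total <= n_perm:
        logger.warning(
            "only %d distinct balanced permutations available (< %d requested); "
            "using exhaustive enumeration", total, n_perm
        )
        P = np.zeros((n, total))
        for b, idx in enumerate(combinations(range(n), n1)):
            P[list(idx), b] = 1.0
        return P, True
    rng = np.random.default_rng(seed)
    P = np.zeros((n, n_perm))
    base = np.arange(n)
    for b in range(n_perm):
        P[rng.permutation(base)[:n1], b] = 1.0
    return P, False


def sam_fdr(
    stats_table: pd.DataFrame,
    s0: float,
    cohort: Cohort,
    class1: str,
    class2: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation FDR in percent for each probeset's |d| threshold."""
    if n_perm < 100:
        raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
    X, n1, n2 = _class_matrices(cohort, class1, class2)
    n = n1 + n2
    P1, exhaustive = _permutation_indicators(n, n1, n_perm, seed)
    B = P1.shape[1]
    P2 = 1.0 - P1

    rowsum = X.sum(axis=1, keepdims=True)
    rowsq = (X**2).sum(axis=1, keepdims=True)
    sum1 = X @ P1
    sq1 = (X**2) @ P1
    sum2 = rowsum - sum1
    sq2 = rowsq - sq1
    m1, m2 = sum1 / n1, sum2 / n2
    ss = (sq1 - sum1**2 / n1) + (sq2 - sum2**2 / n2)
    ss = np.maximum(ss, 0.0)
    s_star = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n - 2))
    denom = s_star + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d_star = np.where(denom > 0, (m2 - m1) / denom, 0.0)
    abs_star = np.sort(np.abs(d_star), axis=0)      # per-column ascending

    d_obs = stats_table["d"].to_numpy(dtype=float)
    zero_scatter = stats_table["zero_scatter"].to_numpy(dtype=bool)
    abs_obs = np.abs(d_obs)
    p = abs_obs.size

    obs_count = np.array([(abs_obs >= t).sum() for t in abs_obs])
    perm_counts = np.empty((B, p))
    for b in range(B):
        perm_counts[b] = p - np.searchsorted(abs_star[:, b], abs_obs, side="left")
    med = np.median(perm_counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = 100.0 * med / obs_count
    q = np.minimum(q, 100.0)

    # monotone non-increasing in |d|: a stricter threshold never reports a
    # larger q than any looser one (step-up style running minimum taken
    # from the weak-|d| end)
    order = np.argsort(-abs_obs, kind="stable")     # descending |d|
    q_sorted = np.minimum.accumulate(q[order][::-1])[::-1]
    q_mono = np.empty_like(q)
    q_mono[order] = q_sorted
    q_mono[zero_scatter] = 100.0

    out = stats_table.copy()
    out["q_percent"] = q_mono
    return out


def sam(
    cohort: Cohort,
    class1: str,
    class2: str,
    n_perm: int = 1000,
    seed: int = 0,
    s0_mode: str = "auto",
    s0: float | None = None,
) -> SamResult:
    """Full SAM run: statistics, fudge factor, permutation FDR."""
    table, s0_used = sam_statistics(cohort, class1, class2, s0_mode=s0_mode, s0=s0)
    table = sam_fdr(table, s0_used, cohort, class1, class2, n_perm=n_perm, seed=seed)
    n = len(cohort.samples_with_label(class1)) + len(cohort.samples_with_label(class2))
    n1 = len(cohort.samples_with_label(class1))
    exhaustive = math.comb(n, n1) <= n_perm
    return SamResult(table=table, s0=s0_used, n_perm=n_perm, seed=seed,
                     class1=class1, class2=class2, exhaustive=exhaustive)


def select_deregulated(
    result: SamResult | pd.DataFrame,
    fdr_max_percent: float = 5.0,
    fold_min: float = 2.0,
) -> tuple[list[str], list[str]]:
    """Published calling rule: FDR below threshold AND at least
    ``fold_min``-fold change in either direction.

    Returns ``(up_list, down_list)`` sorted by probeset ID: up-regulated
    means ratio >= fold_min, down-regulated ratio <= 1/fold_min.
    """
    table = result.table if isinstance(result, SamResult) else result
    if table.empty:
        raise ValidationError("empty SAM result")
    sig = table["q_percent"] < fdr_max_percent
    up = table.index[sig & (table["ratio"] >= fold_min)]
    down = table.index[sig & (table["ratio"] <= 1.0 / fold_min)]
    return sorted(up), sorted(down)
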