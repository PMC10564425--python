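"""Survival analysis: Kaplan-Meier curves, log-rank tests, maximally
selected survival cutpoints, and contingency-table chi-square tests.

The log-rank machinery is implemented directly on sorted arrays so the
cutpoint scan — which evaluates a log-rank statistic at every admissible
split of a continuous score — stays fast at cohort scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import CohortAnnotations, InputError

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CutpointResult",
    "ChiSquareResult",
    "km_estimate",
    "logrank_test",
    "optimal_cutpoint",
    "chisq_independence",
]


@dataclass
class KMCurve:
    """Product-limit survival curve over distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function value just after time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    pvalue: float


@dataclass
class CutpointResult:
    cutoff: float
    statistic: float
    candidates_evaluated: int
    minprop: float


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    expected: np.ndarray


def _km(times: np.ndarray, events: np.ndarray) -> KMCurve:
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    deaths = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_i / n_i
        surv[i], at_risk[i], deaths[i] = s, n_i, d_i
    return KMCurve(event_times.astype(float), surv, at_risk, deaths)


def km_estimate(ann: CohortAnnotations, group: str | None = None) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group (or the whole cohort)."""
    if group is None:
        mask = np.ones(ann.n_samples, dtype=bool)
    else:
        mask = (ann.group == group).to_numpy()
    if not mask.any():
        raise InputError(f"no samples in group {group!r}")
    return _km(ann.time[mask], ann.event[mask])


def _logrank_statistic(
    times: np.ndarray, events: np.ndarray, in_group1: np.ndarray
) -> float:
    """Two-group log-rank chi-square statistic (1 df).

    Vectorized over distinct event times (the cutpoint scan evaluates this
    at every admissible split, so it must be cheap).
    """
    if not np.any(events == 1):
        raise InputError("log-rank test needs at least one event")
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    g = in_group1[order].astype(int)
    n_total = t.size
    g_total = int(g.sum())

    ut = np.unique(t[e == 1])
    first = np.searchsorted(t, ut, side="left")  # count with time < ut
    n_i = n_total - first
    g_cum = np.concatenate(([0], np.cumsum(g)))
    n1_i = g_total - g_cum[first]

    et = t[e == 1]
    d_i = np.searchsorted(et, ut, side="right") - np.searchsorted(et, ut, side="left")
    et1 = t[(e == 1) & (g == 1)]
    d1_i = np.searchsorted(et1, ut, side="right") - np.searchsorted(et1, ut, side="left")

    frac = n1_i / n_i
    o_minus_e = float(np.sum(d1_i - d_i * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = np.where(
            n_i > 1, d_i * frac * (1 - frac) * (n_i - d_i) / (n_i - 1), 0.0
        )
    var = float(np.sum(var_terms))
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def logrank_test(ann: CohortAnnotations, groups: tuple[str, str]) -> LogRankResult:
    """Standard two-group log-rank test (chi-square, 1 df, upper tail)."""
    g1, g2 = groups
    lab = ann.group.to_numpy()
    mask = (lab == g1) | (lab == g2)
    if not (lab == g1).any() or not (lab == g2).any():
        raise InputError(f"both groups {groups} must be non-empty")
    times, events = ann.time[mask], ann.event[mask]
    stat = _logrank_statistic(times, events, lab[mask] == g1)
    return LogRankResult(float(stat), 1, float(stats.chi2.sf(stat, 1)))


def optimal_cutpoint(
    values, ann: CohortAnnotations, minprop: float = 0.10
) -> CutpointResult:
    """Maximally selected log-rank cutpoint on a continuous score.

    Every observed score value whose strict-less split keeps both groups at
    least ``minprop`` of the cohort is evaluated; the cutoff maximizing the
    two-group log-rank statistic wins, ties broken toward the smaller
    cutoff.  No multiplicity correction is applied; ``candidates_evaluated``
    is recorded so callers can correct the selection themselves.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n != ann.n_samples:
        raise InputError("score vector length does not match annotations")
    if int(ann.event.sum()) < 1 or n < 10:
        raise InputError("cutpoint search needs >= 10 samples and >= 1 event")
    times, events = ann.time, ann.event
    min_count = minprop * n
    candidates = []
    for c in np.unique(values):
        n_low = int((values < c).sum())
        if n_low >= min_count and (n - n_low) >= min_count:
            candidates.append(c)
    if not candidates:
        raise InputError("no admissible split satisfies the minprop constraint")
    best_stat, best_cut = -np.inf, None
    for c in candidates:  # ascending; strict > keeps ties at the smaller cutoff
        try:
            stat = _logrank_statistic(times, events, values < c)
        except InputError:
            continue
        if stat > best_stat:
            best_stat, best_cut = stat, c
    if best_cut is None:
        raise InputError("no admissible split has any events")
    return CutpointResult(float(best_cut), float(best_stat), len(candidates), minprop)


def chisq_independence(table) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise InputError("contingency table must be at least 2x2")
    if np.any(table < 0):
        raise InputError("contingency counts must be non-negative")
    if table.sum() <= 0:
        raise InputError("contingency table total must be positive")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InputError("contingency table has a zero row or column sum")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(float(chi2), int(df), float(p), expected)
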