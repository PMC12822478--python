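"""Statistical primitives shared by every analysis stage.

Rank tests branch to exact enumeration on small tie-free inputs and to the
tie-corrected, continuity-corrected normal approximation otherwise; the branch
taken is recorded in :class:`TestResult.method`.  Multiple testing uses
step-up Benjamini-Hochberg throughout ("FDR" in figure legends).  Survival
uses the product-limit estimator and the chi-squared log-rank test with
hypergeometric variance at tied event times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class DegenerateDataWarning(UserWarning):
    """All observations tied / zero; the test statistic is uninformative."""


@dataclass
class TestResult:
    """Outcome of a two-sample or one-sample location test."""

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: Optional[int] = None
    exact: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney / Wilcoxon rank-sum test.

    Exact enumeration when ``min(n_x, n_y) <= 8`` and there are no ties;
    otherwise the normal approximation with tie correction and 0.5 continuity
    correction.
    """
    x, y = _clean(x), _clean(y)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("wilcoxon_rank_sum requires at least one value per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p set to 1",
                      DegenerateDataWarning, stacklevel=2)
        return TestResult(statistic=len(x) * len(y) / 2.0, p_value=1.0,
                          method="rank-sum/degenerate", n1=len(x), n2=len(y))
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (min(len(x), len(y)) <= 8) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method=f"rank-sum/{method}", n1=len(x), n2=len(y), exact=exact)


def wilcoxon_signed_rank(diffs: Sequence[float],
                         alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zeros are dropped (Wilcoxon convention).  Exact when the remaining
    ``n <= 15`` with no tied absolute differences, else normal approximation
    with tie and continuity correction.
    """
    diffs = _clean(diffs)
    if len(diffs) == 0:
        raise ValueError("wilcoxon_signed_rank requires at least one difference")
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; p set to 1",
                      DegenerateDataWarning, stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0,
                          method="signed-rank/degenerate", n1=len(diffs))
    absd = np.abs(nonzero)
    has_ties = len(np.unique(absd)) < len(absd)
    exact = (len(nonzero) <= 15) and not has_ties
    method = "exact" if exact else "approx"
    res = sps.wilcoxon(nonzero, alternative=alternative, zero_method="wilcox",
                       correction=True, method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method=f"signed-rank/{method}", n1=len(nonzero), exact=exact)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.sum():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def spearman_corr(x: Sequence[float], y: Sequence[float],
                  min_pairs: int = 4) -> Tuple[float, float]:
    """Spearman rank correlation with pairwise deletion of missing values.

    Returns ``(nan, nan)`` (flagged, not zero) when either vector is constant
    over the complete pairs.  p-value via the t approximation with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_pairs:
        raise ValueError(f"need >= {min_pairs} complete pairs, got {int(ok.sum())}")
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(xs, ys)
    return float(rho), float(p)


def fisher_exact_2x2(table) -> Tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be nonnegative integers")
    odds, p = sps.fisher_exact(tab.astype(int), alternative="two-sided")
    return float(odds), float(p)


def hypergeom_enrich(overlap: int, set_size: int, selected: int,
                     universe: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap) for over-representation."""
    if not (0 <= overlap <= min(set_size, selected) <= universe):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, set={set_size}, "
            f"selected={selected}, universe={universe}")
    if max(set_size, selected) > universe:
        raise ValueError("set or selection larger than universe")
    return float(sps.hypergeom.sf(overlap - 1, universe, set_size, selected))


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit curve over the distinct event times."""

    event_times: np.ndarray          # ascending distinct event times
    survival: np.ndarray             # S(t) just after each event time
    at_risk: np.ndarray              # number at risk just before each event time
    n_events: np.ndarray             # events at each event time
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median_survival(self) -> float:
        below = self.survival <= 0.5
        return float(self.event_times[below][0]) if below.any() else float("inf")


def km_curve(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Product-limit estimator; censoring at an event time counts as at risk
    for that event time (processed after the events)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_curve requires at least one subject")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    distinct = np.unique(times[events == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in distinct:
        n = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n
        surv.append(s)
        at_risk.append(n)
        n_ev.append(d)
    return SurvivalCurve(event_times=distinct, survival=np.array(surv),
                         at_risk=np.array(at_risk), n_events=np.array(n_ev),
                         censor_times=np.sort(times[events == 0]))


def logrank_test(times_a: Sequence[float], events_a: Sequence[int],
                 times_b: Sequence[float], events_b: Sequence[int]) -> TestResult:
    """Two-group log-rank test: chi2 = (O-E)^2 / V with the hypergeometric
    variance at each distinct event time; p from chi2 with 1 df."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; p set to 1",
                      DegenerateDataWarning, stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, method="logrank/degenerate",
                          n1=ta.size, n2=tb.size)
    chi2 = logrank_statistic(ta, ea, tb, eb)
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(statistic=float(chi2), p_value=p, method="logrank/chi2",
                      n1=ta.size, n2=tb.size)


def logrank_statistic(times_a, events_a, times_b, events_b) -> float:
    """The log-rank chi-squared statistic (no p-value); also used by the
    permutation oracle in the test suite."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    group_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(all_times[all_events == 1]):
        at_risk = all_times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & group_a).sum())
        d = int(((all_times == t) & (all_events == 1)).sum())
        d_a = int(((all_times == t) & (all_events == 1) & group_a).sum())
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e ** 2 / var


def median_split(values: Sequence[float]) -> np.ndarray:
    """Boolean high-group mask for a median split; ties go to the low stratum."""
    arr = np.asarray(values, dtype=float)
    med = np.nanmedian(arr)
    if np.all(arr[np.isfinite(arr)] == med):
        raise ValueError("degenerate split: all values equal")
    return arr > med
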