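"""Risk-group assignment from model outputs.

Classification uses the fixed probability cutoff 0.5.  Survival tasks
use a percentile-grid threshold search on the learning set: candidate
percentiles span round(100 * n0/(n0+n1))/100 +- 0.2 (clipped to
[0.05, 0.95], step 0.01, n0 = censored / n1 = events), and the selected
threshold is the risk quantile whose two-group split minimizes the
log-rank p-value.  Because the threshold is chosen to minimize that
p-value, the learning-set p-value is anti-conservative; report the
held-out p-value for inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats as sstats

__all__ = [
    "LogRankResult", "ThresholdSearchResult", "KMEstimate",
    "percentile_bounds", "log_rank_test", "threshold_search",
    "assign_groups", "kaplan_meier",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percentile_bounds(n0: int, n1: int):
    """Percentile-grid bounds from censored (n0) and event (n1) counts.

    Returns ``(p_lower, p_upper, grid)`` with
    p_lower = max(round(100 n0/(n0+n1))/100 - 0.2, 0.05) and
    p_upper = min(... + 0.2, 0.95); the grid steps by 0.01 inclusive.
    """
    if n0 + n1 <= 0:
        raise ValueError("empty cohort")
    base = _round_half_away(100.0 * n0 / (n0 + n1))
    lo = max(base - 20, 5)
    hi = min(base + 20, 95)
    grid = np.array([i / 100.0 for i in range(lo, hi + 1)])
    return lo / 100.0, hi / 100.0, grid


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    p_value: float
    hazard_ratio: float
    hr_ci: tuple
    observed: tuple   # (O1, O2)
    expected: tuple   # (E1, E2)


def log_rank_test(groups, events, times) -> LogRankResult:
    """Two-group log-rank test with the O/E hazard-ratio estimate.

    HR = (O1/E1)/(O2/E2) with a log-scale 95% CI from
    sqrt(1/E1 + 1/E2).  Degenerate splits (no variance, e.g. no
    overlap of the groups' observed time spans) return p = 1.
    """
    groups = np.asarray(groups).astype(int)
    events = np.asarray(events).astype(bool)
    times = np.asarray(times, float)
    if len(np.unique(groups)) != 2:
        raise ValueError("two nonempty groups required")

    o1 = e1 = v = 0.0
    for u in np.unique(times[events]):
        at_risk = times >= u
        n_j = at_risk.sum()
        n1j = (at_risk & (groups == 1)).sum()
        d_j = (events & (times == u)).sum()
        d1j = (events & (times == u) & (groups == 1)).sum()
        o1 += d1j
        e1 += d_j * n1j / n_j
        if n_j > 1:
            v += d_j * (n1j / n_j) * (1 - n1j / n_j) * (n_j - d_j) / (n_j - 1)
    o_total = events.sum()
    o2, e2 = o_total - o1, o_total - e1
    if v <= 0:
        return LogRankResult(0.0, 1.0, np.nan, (np.nan, np.nan),
                             (o1, o2), (e1, e2))
    chi2 = (o1 - e1) ** 2 / v
    p = float(sstats.chi2.sf(chi2, df=1))
    if e1 > 0 and e2 > 0 and o1 > 0 and o2 > 0:
        hr = (o1 / e1) / (o2 / e2)
        se = np.sqrt(1.0 / e1 + 1.0 / e2)
        ci = (hr * np.exp(-1.959963984540054 * se),
              hr * np.exp(1.959963984540054 * se))
    else:
        hr, ci = np.nan, (np.nan, np.nan)
    return LogRankResult(float(chi2), p, float(hr), ci, (float(o1), float(o2)),
                         (float(e1), float(e2)))


@dataclass(frozen=True)
class ThresholdSearchResult:
    p_lower: float
    p_upper: float
    grid: np.ndarray
    p_star: float
    threshold: float
    p_values: np.ndarray   # log-rank p per candidate (NaN for degenerate splits)


def threshold_search(risks, events, times) -> ThresholdSearchResult:
    """Exhaustive percentile-grid search for the best-separating risk cutoff.

    Every candidate percentile is evaluated; the lowest log-rank
    p-value wins, ties broken toward the smallest percentile.  The
    threshold is the (lower-interpolation) quantile of learning-set
    risks at the chosen percentile.
    """
    risks = np.asarray(risks, float)
    events = np.asarray(events).astype(bool)
    times = np.asarray(times, float)
    n1 = int(events.sum())
    n0 = len(events) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both events and censorings are required")
    lo, hi, grid = percentile_bounds(n0, n1)
    pvals = np.full(len(grid), np.nan)
    for k, p in enumerate(grid):
        r = np.quantile(risks, p, method="lower")
        g = (risks > r).astype(int)
        if g.min() == g.max():
            continue
        pvals[k] = log_rank_test(g, events, times).p_value
    if np.all(np.isnan(pvals)):
        raise ValueError("every candidate split leaves a single group")
    best = int(np.nanargmin(pvals))   # first minimum = lowest percentile
    p_star = float(grid[best])
    return ThresholdSearchResult(lo, hi, grid, p_star,
                                 float(np.quantile(risks, p_star, method="lower")),
                                 pvals)


def assign_groups(values, kind: str, threshold: float | None = None) -> np.ndarray:
    """Low-risk 0 / high-risk 1; boundary values go to low risk.

    Classification: group 1 iff probability > 0.5.  Survival: group 1
    iff risk > threshold.
    """
    values = np.asarray(values, float)
    if kind == "classification":
        return (values > 0.5).astype(int)
    if kind == "survival":
        if threshold is None:
            raise ValueError("survival grouping requires a threshold")
        return (values > threshold).astype(int)
    raise ValueError(f"unknown task kind {kind!r}")


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate with log-hazard-based 95% CI."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right") - 1
        return np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])

    def to_frame(self):
        """Curve as a tidy table (for CSV export / plotting)."""
        import pandas as pd

        return pd.DataFrame({
            "time": self.times, "survival": self.survival,
            "at_risk": self.at_risk, "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
        })


def kaplan_meier(events, times) -> KMEstimate:
    """Kaplan-Meier curve with the exponential-Greenwood (log-hazard) CI."""
    events = np.asarray(events).astype(bool)
    times = np.asarray(times, float)
    if times.size == 0:
        raise ValueError("empty outcome vector")
    kmf = KaplanMeierFitter().fit(times, events)
    timeline = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    ci = kmf.confidence_interval_
    table = kmf.event_table
    at_risk = table["at_risk"].reindex(timeline).to_numpy(float)
    return KMEstimate(timeline, surv, at_risk,
                      ci.iloc[:, 0].to_numpy(float), ci.iloc[:, 1].to_numpy(float))
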