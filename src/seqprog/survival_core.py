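"""Task losses and hazard machinery for the sequential prognosis models.

Implements the three task-kind losses used to train the networks —
class-weighted binary cross-entropy for classification, the Cox
negative partial log-likelihood (NPLL) for right-censored survival
outcomes, and the (soft) Dice loss for segmentation — together with the
Breslow estimator of the cumulative baseline hazard and the assembly of
per-patient survival curves s(t, x) = exp[-H_b(t) e^{g(x)}].

All losses are written against :mod:`seqprog.autodiff` dispatch
functions, so they double as pure numpy references (ndarray inputs) and
as differentiable training losses (Tensor inputs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autodiff as F

__all__ = [
    "BatchClassStats", "BaselineHazard", "SurvivalCurve",
    "weighted_bce", "risk_set", "npll", "breslow", "survival_curve",
    "dice_loss", "voxel_classify",
]

#: floor applied to probabilities before taking logarithms
PROB_CLAMP = 1e-7
#: smoothing added to the Dice denominator so empty/empty maps give 0
DICE_SMOOTH = 1e-5


@dataclass(frozen=True)
class BatchClassStats:
    """Class counts of the *training* set driving the BCE weight (n0/n1)^y."""

    n0: int
    n1: int

    def __post_init__(self):
        if self.n0 < 0 or self.n1 < 0:
            raise ValueError("class counts must be nonnegative")
        if self.n1 == 0:
            raise ValueError("no positive class in training set")

    @classmethod
    def from_labels(cls, labels) -> "BatchClassStats":
        labels = np.asarray(labels)
        return cls(int((labels == 0).sum()), int((labels == 1).sum()))


def _clamp(p):
    """Clamp probabilities into (PROB_CLAMP, 1-PROB_CLAMP) without breaking the tape."""
    if isinstance(p, F.Tensor):
        lo = F.where_const(p.data < PROB_CLAMP, PROB_CLAMP + 0.0 * p, p)
        return F.where_const(lo.data > 1 - PROB_CLAMP, (1 - PROB_CLAMP) + 0.0 * lo, lo)
    return np.clip(p, PROB_CLAMP, 1 - PROB_CLAMP)


def weighted_bce(probs, labels, stats: BatchClassStats):
    """Class-weighted binary cross-entropy.

    L = -(1/n_b) sum_i (n0/n1)^{y_i} [ y_i ln f_i + (1-y_i) ln(1-f_i) ]
    """
    labels = np.asarray(labels, dtype=float)
    n_b = labels.shape[0]
    w = (stats.n0 / stats.n1) ** labels
    f = _clamp(probs)
    terms = w * (labels * F.log(f) + (1.0 - labels) * F.log(1.0 - f))
    return -F.tsum(terms) / n_b


def risk_set(times, i: int) -> np.ndarray:
    """Indices at risk at the i-th observed time: { j : y_j >= y_i }."""
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("observed times must be positive")
    return np.flatnonzero(times >= times[i])


def npll(risks, events, times):
    """Cox negative partial log-likelihood, averaged over events.

    L = (1/n_e) sum_i eps_i ln sum_{j in R_i} exp(g_j - g_i).
    Invariant to adding a constant to all risks.
    """
    events = np.asarray(events, dtype=bool)
    times = np.asarray(times, dtype=float)
    n_e = int(events.sum())
    if n_e == 0:
        raise ValueError("no events in batch")
    # risk-set membership matrix restricted to event rows
    ev_idx = np.flatnonzero(events)
    mask = (times[None, :] >= times[ev_idx, None]).astype(float)  # (n_e, n)
    g = risks
    shift = float(np.max(g.data if isinstance(g, F.Tensor) else g))
    s = F.exp(g - shift)
    denom = F.matmul(mask, s)            # (n_e,)
    g_ev = g[ev_idx] if isinstance(g, F.Tensor) else np.asarray(g)[ev_idx]
    terms = F.log(denom) - (g_ev - shift)
    return F.tsum(terms) / n_e


@dataclass(frozen=True)
class BaselineHazard:
    """Breslow step estimate of the cumulative baseline hazard H_b(t).

    Right-continuous, zero before the first event time.
    """

    event_times: np.ndarray
    cum_hazard: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.cum_hazard) < 0):
            raise ValueError("cumulative hazard must be nondecreasing")

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float),
                              side="right")
        padded = np.concatenate([[0.0], self.cum_hazard])
        return padded[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times, "cum_hazard": self.cum_hazard})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BaselineHazard":
        return cls(frame["time"].to_numpy(float), frame["cum_hazard"].to_numpy(float))


def breslow(risks, events, times) -> BaselineHazard:
    """Breslow estimator with tied event times pooled.

    H_b(t) = sum over distinct event times u <= t of m_u / sum_{j: y_j >= u} exp(g_j),
    where m_u counts events at u.
    """
    risks = np.asarray(risks.data if isinstance(risks, F.Tensor) else risks, float)
    events = np.asarray(events, dtype=bool)
    times = np.asarray(times, dtype=float)
    if times.size == 0 or not events.any():
        raise ValueError("at least one event required")
    shift = risks.max()
    eg = np.exp(risks - shift)
    uniq = np.unique(times[events])
    increments = np.empty_like(uniq)
    for k, u in enumerate(uniq):
        m = int(((times == u) & events).sum())
        denom = eg[times >= u].sum() * np.exp(shift)
        increments[k] = m / denom
    return BaselineHazard(uniq, np.cumsum(increments))


@dataclass(frozen=True)
class SurvivalCurve:
    """Survival probabilities s(t) on a time grid; s(0)=1, nonincreasing."""

    times: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        p = self.probabilities
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(p) > 1e-12):
            raise ValueError("survival curve must be nonincreasing")

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.probabilities[idx]


def survival_curve(risk: float, baseline: BaselineHazard, grid=None) -> SurvivalCurve:
    """Per-patient survival curve s(t) = exp(-H_b(t) e^g)."""
    if grid is None:
        grid = np.concatenate([[0.0], baseline.event_times])
    grid = np.asarray(grid, dtype=float)
    s = np.exp(-baseline(grid) * np.exp(float(risk)))
    return SurvivalCurve(grid, s)


def dice_loss(pred, truth):
    """Soft Dice loss, batch-averaged; in [-1, 0].

    Accepts a single volume or a batch with a leading batch axis; `pred`
    may be soft probabilities (training) or binary maps (evaluation).
    """
    truth = np.asarray(truth, dtype=float)
    pshape = pred.data.shape if isinstance(pred, F.Tensor) else np.shape(pred)
    if tuple(pshape) != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    if truth.ndim == 3:
        inter = F.tsum(pred * truth)
        denom = F.tsum(pred) + truth.sum() + DICE_SMOOTH
        return -2.0 * inter / denom
    axes = tuple(range(1, truth.ndim))
    inter = F.tsum(pred * truth, axis=axes)
    denom = F.tsum(pred, axis=axes) + truth.sum(axis=axes) + DICE_SMOOTH
    return F.tmean(-2.0 * inter / denom)


def voxel_classify(prob_map) -> np.ndarray:
    """Binary voxel rule: 1 iff p > 0.5 (p = 0.5 goes to background)."""
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return (prob_map > 0.5).astype(np.uint8)
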