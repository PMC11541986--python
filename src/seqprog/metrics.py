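"""Evaluation metrics for the three task kinds.

Classification is scored with AUC and binary balanced accuracy,
survival tasks with the concordance index (CI), its inverse-probability-
of-censoring-weighted variant (CICW, Uno's estimator) and the
cumulative/dynamic AUC (CDA), and segmentation with the Dice similarity
coefficient.  The censoring-weighted estimators delegate to
scikit-survival; tests check them against independent brute-force pair
enumerations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sksurv.metrics import (
    concordance_index_censored,
    concordance_index_ipcw as _sksurv_ipcw,
    cumulative_dynamic_auc as _sksurv_cda,
)
from sksurv.nonparametric import kaplan_meier_estimator
from sksurv.util import Surv

__all__ = [
    "CensoringDistribution", "auroc", "balanced_accuracy",
    "concordance_index", "concordance_index_ipcw", "cumulative_dynamic_auc",
    "dice_similarity", "default_time_grid",
]


def _surv(events, times):
    return Surv.from_arrays(np.asarray(events, bool), np.asarray(times, float))


@dataclass(frozen=True)
class CensoringDistribution:
    """Kaplan-Meier estimate G(t) of the censoring survival function.

    Fit on outcomes with the event indicator reversed; used as the IPCW
    weight source.
    """

    times: np.ndarray
    probabilities: np.ndarray

    @classmethod
    def fit(cls, events, times) -> "CensoringDistribution":
        cens = ~np.asarray(events, bool)
        t, p = kaplan_meier_estimator(cens, np.asarray(times, float))
        return cls(t, p)

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right") - 1
        out = np.where(idx < 0, 1.0, self.probabilities[np.clip(idx, 0, None)])
        return out


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney normalization, ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def balanced_accuracy(probs, labels, cutoff: float = 0.5) -> float:
    """(sensitivity + specificity) / 2 at the given probability cutoff."""
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    preds = np.asarray(probs, float) > cutoff
    sens = (preds & labels).sum() / labels.sum()
    spec = (~preds & ~labels).sum() / (~labels).sum()
    return float((sens + spec) / 2.0)


def concordance_index(risks, events, times) -> float:
    """Harrell's C: fraction of comparable pairs ordered correctly.

    A pair (i, j) is comparable iff y_i < y_j and patient i had the
    event; concordant iff g_i > g_j, tied risks count 1/2.
    """
    events = np.asarray(events, bool)
    if not events.any():
        raise ValueError("no comparable pairs")
    c = concordance_index_censored(events, np.asarray(times, float),
                                   np.asarray(risks, float))
    return float(c[0])


def default_tau(times) -> float:
    """Default truncation horizon for CICW: 80th percentile of observed times."""
    return float(np.quantile(np.asarray(times, float), 0.8))


def concordance_index_ipcw(risks, train_events, train_times,
                           test_events, test_times, tau: float | None = None) -> float:
    """Uno's censoring-weighted concordance, weights G(y_i)^-2, truncated at tau."""
    if tau is None:
        tau = default_tau(test_times)
    c = _sksurv_ipcw(_surv(train_events, train_times),
                     _surv(test_events, test_times),
                     np.asarray(risks, float), tau=tau)
    return float(c[0])


def default_time_grid(events, times, n: int = 9) -> np.ndarray:
    """Deciles of observed event times, extremes excluded."""
    ev_times = np.asarray(times, float)[np.asarray(events, bool)]
    qs = np.linspace(0.1, 0.9, n)
    grid = np.unique(np.quantile(ev_times, qs))
    # keep strictly inside the observed follow-up range
    tmax = np.asarray(times, float).max()
    return grid[grid < tmax]


def cumulative_dynamic_auc(risks, train_events, train_times,
                           test_events, test_times, time_grid=None):
    """IPCW cumulative/dynamic AUC at each grid time plus its mean.

    At horizon t, cases are subjects with an event by t and controls
    those still event-free after t.
    """
    if time_grid is None:
        time_grid = default_time_grid(test_events, test_times)
    time_grid = np.asarray(time_grid, float)
    aucs, mean_auc = _sksurv_cda(_surv(train_events, train_times),
                                 _surv(test_events, test_times),
                                 np.asarray(risks, float), time_grid)
    return np.asarray(aucs, float), float(mean_auc)


def dice_similarity(pred, truth) -> float:
    """2|A n B| / (|A| + |B|); 1.0 when both maps are empty."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (pred & truth).sum() / denom)
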