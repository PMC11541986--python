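"""Experimental protocol at configurable scale.

Reproduces the model-selection workflow around the sequential network:
a stratified 85/15 learning/holdout split (stratification on the LNI
class label and the BCR-FS event indicator), stratified k-fold
cross-validation on the learning set, nested hyperparameter search
with 25 sequentially sampled trials (the first 5 uniform random, the
rest from a scrambled Sobol low-discrepancy sequence), selection by
AUC (classification) or concordance index (survival), and per-task
metric reports.  With the defaults (5 outer folds, 5 inner folds, 25
trials) a full search fits 5 x 5 x 25 = 625 model instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .metrics import (auroc, balanced_accuracy, concordance_index,
                      concordance_index_ipcw, cumulative_dynamic_auc)
from .synthetic_cohort import SURVIVAL_TASKS

__all__ = [
    "SplitSpec", "HyperparameterSpace", "TrialRecord",
    "holdout_split", "stratified_kfold", "sample_hyperparameters",
    "nested_cv", "evaluate",
]


@dataclass(frozen=True)
class SplitSpec:
    learning_fraction: float = 0.85
    stratify_on: tuple = ("lni_label", "bcr_event")
    k_outer: int = 5
    k_inner: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.learning_fraction < 1:
            raise ValueError("learning fraction must lie strictly in (0, 1)")
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("fold counts must be >= 2")


def _strata(cohort: pd.DataFrame, keys) -> pd.Series:
    return cohort[list(keys)].astype(int).astype(str).agg("|".join, axis=1)


def holdout_split(cohort: pd.DataFrame, spec: SplitSpec):
    """Stratified learning/holdout split; learning size = floor(f * n).

    Each stratum contributes floor-proportionally, with the remaining
    patients allocated by largest fractional part, so every stratum's
    learning proportion deviates from the target by at most one
    patient.
    """
    rng = np.random.default_rng(spec.seed)
    strata = _strata(cohort, spec.stratify_on)
    n_learning = int(np.floor(spec.learning_fraction * len(cohort)))
    groups = {s: rng.permutation(np.flatnonzero((strata == s).to_numpy()))
              for s in sorted(strata.unique())}
    if any(len(g) < 2 for g in groups.values()):
        raise ValueError("every stratum needs at least 2 patients")
    quotas = {s: spec.learning_fraction * len(g) for s, g in groups.items()}
    take = {s: int(np.floor(q)) for s, q in quotas.items()}
    remainder = n_learning - sum(take.values())
    by_frac = sorted(quotas, key=lambda s: quotas[s] - take[s], reverse=True)
    for s in by_frac[:remainder]:
        take[s] += 1
    learning_idx = np.concatenate([groups[s][:take[s]] for s in groups])
    holdout_idx = np.concatenate([groups[s][take[s]:] for s in groups])
    return (cohort.iloc[np.sort(learning_idx)].copy(),
            cohort.iloc[np.sort(holdout_idx)].copy())


def stratified_kfold(cohort: pd.DataFrame, k: int = 5,
                     keys=("lni_label", "bcr_event"), seed: int = 0):
    """k disjoint stratified folds with sizes differing by at most one.

    Shuffled stratum members are dealt in a single continuing
    round-robin over the folds, which balances both the overall fold
    sizes and each stratum's spread.  Strata smaller than k (rare
    outcome combinations) are pooled into one overflow stratum before
    dealing.
    """
    rng = np.random.default_rng(seed)
    strata = _strata(cohort, keys).copy()
    sizes = strata.value_counts()
    small = sizes.index[sizes < k]
    if len(small) == len(sizes):
        strata[:] = "__pooled__"
    elif len(small):
        # fold rare outcome combinations into the largest stratum
        strata[strata.isin(small)] = sizes.index[0]
    if k > strata.value_counts().min():
        raise ValueError("k exceeds the smallest (pooled) stratum size")
    folds = [[] for _ in range(k)]
    pointer = 0
    for s in sorted(strata.unique()):
        members = rng.permutation(np.flatnonzero((strata == s).to_numpy()))
        for m in members:
            folds[pointer % k].append(m)
            pointer += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass(frozen=True)
class HyperparameterSpace:
    """Named ranges: (low, high) tuples for continuous parameters,
    (low, high, 'int') for integers, or an explicit list of choices."""

    ranges: dict
    budget: int = 25
    n_random: int = 5


@dataclass(frozen=True)
class TrialRecord:
    index: int
    values: dict
    score: float = np.nan


def _map_unit(space: HyperparameterSpace, u: np.ndarray) -> dict:
    values = {}
    for ui, (name, rng_) in zip(u, space.ranges.items()):
        if isinstance(rng_, list):
            values[name] = rng_[min(int(ui * len(rng_)), len(rng_) - 1)]
        else:
            lo, hi = rng_[0], rng_[1]
            v = lo + ui * (hi - lo)
            if len(rng_) > 2 and rng_[2] == "int":
                v = int(round(v))
            values[name] = v
    return values


def sample_hyperparameters(space: HyperparameterSpace, history: list,
                           trial_index: int, seed: int = 0) -> dict:
    """Trial values: the first `n_random` trials are uniform random, the
    rest follow a scrambled Sobol sequence over the space (deterministic
    under the seed)."""
    if trial_index >= space.budget:
        raise ValueError("hyperparameter budget exhausted")
    d = len(space.ranges)
    if trial_index < space.n_random:
        rng = np.random.default_rng((seed, trial_index))
        u = rng.uniform(size=d)
    else:
        engine = qmc.Sobol(d, scramble=True, seed=seed)
        skip = trial_index - space.n_random
        if skip > 0:
            engine.fast_forward(skip)
        u = engine.random(1)[0]
    return _map_unit(space, u)


def nested_cv(cohort: pd.DataFrame, spec: SplitSpec,
              space: HyperparameterSpace, model_factory,
              keys=("lni_label", "bcr_event")) -> dict:
    """Nested stratified cross-validation with quasi-random search.

    `model_factory(params)` must return an object with ``fit(df)`` and
    ``score(df) -> float`` (higher is better).  For every outer fold,
    every trial's parameter set is scored by inner k-fold CV; the best
    trial is refit on the outer training set and scored on the outer
    test fold.  Exactly ``k_outer * k_inner * budget`` instances are
    fitted during the search (refits excluded).
    """
    outer = stratified_kfold(cohort, spec.k_outer, keys, spec.seed)
    n_fitted = 0
    outer_scores, chosen = [], []
    for fold_id, test_idx in enumerate(outer):
        test_df = cohort.iloc[test_idx]
        train_idx = np.setdiff1d(np.arange(len(cohort)), test_idx)
        train_df = cohort.iloc[train_idx].reset_index(drop=True)
        inner = stratified_kfold(train_df, spec.k_inner, keys,
                                 spec.seed + 1000 + fold_id)
        trials = []
        for t in range(space.budget):
            params = sample_hyperparameters(space, trials, t,
                                            seed=spec.seed * 100 + fold_id)
            inner_scores = []
            for in_test in inner:
                in_train = np.setdiff1d(np.arange(len(train_df)), in_test)
                model = model_factory(params)
                model.fit(train_df.iloc[in_train])
                inner_scores.append(model.score(train_df.iloc[in_test]))
                n_fitted += 1
            trials.append(TrialRecord(t, params, float(np.mean(inner_scores))))
        best = max(trials, key=lambda tr: tr.score)
        model = model_factory(best.values)
        model.fit(train_df)
        outer_scores.append(float(model.score(test_df)))
        chosen.append(best)
    return {
        "outer_scores": outer_scores,
        "mean_score": float(np.mean(outer_scores)),
        "std_score": float(np.std(outer_scores)),
        "best_trials": chosen,
        "n_fitted": n_fitted,
    }


def evaluate(graph, test_cohort: pd.DataFrame,
             train_cohort: pd.DataFrame | None = None,
             t_p: float = 0.0) -> dict:
    """Per-task metric report: {AUC, BA} for classification, {CI, CICW,
    CDA} for survival tasks.

    The censoring distribution behind CICW/CDA is estimated on the
    training outcomes when `train_cohort` is given (IPCW convention),
    otherwise on the test outcomes.
    """
    preds = graph.predict_risks(test_cohort, t_p=t_p)
    ref = train_cohort if train_cohort is not None else test_cohort
    report = {}
    for spec in graph.tasks:
        name = spec.name
        if spec.kind == "classification":
            labels = test_cohort[f"{name}_label"].to_numpy(float)
            probs = preds[f"{name}_prob"].to_numpy()
            report[name] = {"AUC": auroc(probs, labels),
                            "BA": balanced_accuracy(probs, labels),
                            "n": int(len(labels))}
        else:
            ev = test_cohort[f"{name}_event"].to_numpy(bool)
            tm = test_cohort[f"{name}_time"].to_numpy(float)
            ev_tr = ref[f"{name}_event"].to_numpy(bool)
            tm_tr = ref[f"{name}_time"].to_numpy(float)
            risks = preds[f"{name}_risk"].to_numpy()
            entry = {"CI": concordance_index(risks, ev, tm), "n": int(len(ev))}
            try:
                entry["CICW"] = concordance_index_ipcw(risks, ev_tr, tm_tr, ev, tm)
            except ValueError:
                entry["CICW"] = np.nan
            try:
                _, entry["CDA"] = cumulative_dynamic_auc(risks, ev_tr, tm_tr, ev, tm)
            except ValueError:
                entry["CDA"] = np.nan
            report[name] = entry
    return report
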