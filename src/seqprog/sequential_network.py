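"""The Sequential Network: chained single-task prognosis models.

Six tasks follow the natural history of high-grade prostate cancer:
lymph-node invasion (classification), then five right-censored survival
outcomes (BCR-FS, MFS, dADT-FS, CRPC-FS, PCSS).  Each task's model
takes three kinds of input: clinical data (always), task-specific
imaging features (handcrafted or deep radiomics), and the outputs of
the preceding tasks' models.  Because every connection is
differentiable, the whole network is trained jointly by gradient
descent; at inference, known short-term outcomes can be substituted for
upstream model outputs, yielding *dynamic predictions* that sharpen as
a patient's history unfolds.

Substitution rule for the extra input a_j(t_p) from predecessor j at
prognosis time t_p:

* classification: -C if the label is 0 and t_p > 0, +C if it is 1 and
  t_p > 0, and the upstream pre-activation q_j when t_p = 0 (C = 5);
* survival: +C if the event occurred before t_p (y_j < t_p, eps_j = 1),
  otherwise the upstream risk f_j (C = 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import autodiff as F
from .autodiff import Tensor
from .neural_core import MLP, MLPConfig, posterior_predictive
from .survival_core import (BaselineHazard, BatchClassStats, breslow, npll,
                            survival_curve, weighted_bce)
from .synthetic_cohort import CLINICAL_FEATURES, SURVIVAL_TASKS, TASKS

__all__ = [
    "TaskSpec", "SequenceGraph", "DynamicContext",
    "CLASS_SUBSTITUTION", "SURV_SUBSTITUTION",
    "dynamic_input_value", "assemble_inputs", "context_from_cohort",
]

#: finite stand-ins for the +-infinity substitutions
CLASS_SUBSTITUTION = 5.0
SURV_SUBSTITUTION = 10.0

_CANONICAL_ORDER = {t: i for i, t in enumerate(TASKS)}


@dataclass(frozen=True)
class TaskSpec:
    """One task in the sequence: kind, input sources and predecessor edges."""

    name: str
    kind: str                       # "classification" | "survival"
    input_sources: tuple = ("CD",)  # subset of {"CD", "HCR", "DLR"}
    predecessors: tuple = ()        # names of earlier tasks feeding this one

    def __post_init__(self):
        if self.kind not in ("classification", "survival"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if "CD" not in self.input_sources:
            raise ValueError("clinical data is a mandatory input source")


@dataclass(frozen=True)
class DynamicContext:
    """Outcomes known at prognosis time t_p (months).

    `class_labels` maps a classification task to per-patient labels
    (NaN = unknown); `events`/`times` map a survival task to its event
    indicator and observed time.  Outcomes are only consulted for tasks
    preceding the queried one.
    """

    t_p: float = 0.0
    class_labels: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
    times: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.t_p < 0:
            raise ValueError("prognosis time must be >= 0")
        for task, ev in self.events.items():
            t = np.asarray(self.times[task], float)
            known = np.asarray(ev, float) == 1
            if np.any(known & (t > self.t_p)):
                raise ValueError(
                    f"context for {task!r} claims an event after t_p={self.t_p}")


def context_from_cohort(cohort: pd.DataFrame, t_p: float) -> DynamicContext:
    """Build the context a clinician would have at time t_p from outcome columns.

    The LNI label is known from surgery (t = 0 in the follow-up clock),
    so it enters any context with t_p > 0; a survival event is known
    only if it occurred by t_p.
    """
    labels = {}
    events, times = {}, {}
    if t_p > 0 and "lni_label" in cohort.columns:
        labels["lni"] = cohort["lni_label"].to_numpy(float)
    for task in SURVIVAL_TASKS:
        ev_col, t_col = f"{task}_event", f"{task}_time"
        if ev_col in cohort.columns:
            ev = cohort[ev_col].to_numpy(float)
            t = cohort[t_col].to_numpy(float)
            known = (ev == 1) & (t < t_p)
            events[task] = np.where(known, 1.0, 0.0)
            times[task] = np.where(known, t, np.inf)
    return DynamicContext(t_p=t_p, class_labels=labels, events=events, times=times)


def dynamic_input_value(pred_spec: TaskSpec, t_p: float, upstream, *,
                        labels=None, events=None, times=None) -> np.ndarray:
    """Resolve a_j(t_p) for one predecessor task, vectorized over patients."""
    upstream = np.asarray(upstream, float)
    if t_p == 0:
        return upstream
    if pred_spec.kind == "classification":
        if labels is None:
            return upstream
        labels = np.asarray(labels, float)
        sub = np.where(labels == 1, CLASS_SUBSTITUTION, -CLASS_SUBSTITUTION)
        return np.where(np.isnan(labels), upstream, sub)
    if events is None:
        return upstream
    occurred = (np.asarray(events, float) == 1) & (np.asarray(times, float) < t_p)
    return np.where(occurred, SURV_SUBSTITUTION, upstream)


def assemble_inputs(spec: TaskSpec, cd, imaging: dict, pred_values: list):
    """Concatenate [CD | imaging | a_i(t_p)] in fixed documented order."""
    parts = [cd]
    for source in ("HCR", "DLR"):
        if source in spec.input_sources:
            if source not in imaging:
                raise ValueError(f"task {spec.name!r} needs {source} features")
            parts.append(imaging[source])
    for v in pred_values:
        if v is None:
            raise ValueError("unresolved predecessor value")
        col = v.reshape(-1, 1) if isinstance(v, Tensor) else np.asarray(v, float).reshape(-1, 1)
        parts.append(col)
    return F.concatenate(parts, axis=1)


def _substitute_tensor(pred_spec: TaskSpec, ctx: DynamicContext, upstream):
    """a_j(t_p) on the tape: substituted entries become constants."""
    if ctx.t_p == 0:
        return upstream
    if pred_spec.kind == "classification":
        labels = ctx.class_labels.get(pred_spec.name)
        if labels is None:
            return upstream
        labels = np.asarray(labels, float)
        sub = np.where(labels == 1, CLASS_SUBSTITUTION, -CLASS_SUBSTITUTION)
        return F.where_const(~np.isnan(labels), sub, upstream)
    events = ctx.events.get(pred_spec.name)
    if events is None:
        return upstream
    occurred = ((np.asarray(events, float) == 1)
                & (np.asarray(ctx.times[pred_spec.name], float) < ctx.t_p))
    return F.where_const(occurred, SURV_SUBSTITUTION, upstream)


def _full_chain(names_kinds, sources=None):
    specs, earlier = [], []
    for name, kind in names_kinds:
        src = ("CD",) if sources is None else sources.get(name, ("CD",))
        specs.append(TaskSpec(name, kind, src, tuple(earlier)))
        earlier.append(name)
    return specs


class SequenceGraph:
    """Ordered task specs plus their attached models and baselines."""

    def __init__(self, tasks: list[TaskSpec]):
        order = [_CANONICAL_ORDER.get(t.name) for t in tasks]
        if any(o is None for o in order) or order != sorted(order):
            raise ValueError("tasks must follow the canonical sequence order")
        names = [t.name for t in tasks]
        for i, t in enumerate(tasks):
            for p in t.predecessors:
                if p not in names[:i]:
                    raise ValueError(f"predecessor {p!r} of {t.name!r} is not earlier")
        self.tasks = list(tasks)
        self.models: dict[str, MLP] = {}
        self.baselines: dict[str, BaselineHazard] = {}
        self.thresholds: dict[str, float] = {}
        self.class_stats: dict[str, BatchClassStats] = {}
        self.feature_columns = list(CLINICAL_FEATURES)
        self.imaging_columns: dict[str, list] = {}
        self._norm: tuple | None = None

    # -- construction --------------------------------------------------------
    @classmethod
    def default(cls) -> "SequenceGraph":
        """Clinical-data-only graph with full-chain predecessor edges."""
        kinds = [("lni", "classification")] + [(t, "survival") for t in SURVIVAL_TASKS]
        return cls(_full_chain(kinds))

    @classmethod
    def default_imaging(cls) -> "SequenceGraph":
        """Input assignment with HCR for LNI and DLR for BCR-FS."""
        kinds = [("lni", "classification")] + [(t, "survival") for t in SURVIVAL_TASKS]
        sources = {"lni": ("CD", "HCR"), "bcr": ("CD", "DLR")}
        g = cls(_full_chain(kinds, sources))
        g.imaging_columns = {"HCR": [f"hcr_{i}" for i in range(1, 7)],
                             "DLR": [f"dlr_{i}" for i in range(1, 7)]}
        return g

    def spec(self, name: str) -> TaskSpec:
        return next(t for t in self.tasks if t.name == name)

    def input_dim(self, spec: TaskSpec) -> int:
        d = len(self.feature_columns)
        for s in ("HCR", "DLR"):
            if s in spec.input_sources:
                d += len(self.imaging_columns.get(s, []))
        return d + len(spec.predecessors)

    def build_models(self, hidden_layers=(), bayesian: bool = False,
                     seed: int = 0, activation: str = "prelu",
                     dropout: float = 0.0) -> "SequenceGraph":
        for i, t in enumerate(self.tasks):
            cfg = MLPConfig(self.input_dim(t), tuple(hidden_layers),
                            activation, dropout, bayesian)
            self.models[t.name] = MLP(cfg, seed=seed * 1000 + i)
        return self

    # -- data plumbing -------------------------------------------------------
    def _design(self, cohort: pd.DataFrame, fit_norm: bool = False):
        x = cohort[self.feature_columns].to_numpy(float)
        if fit_norm or self._norm is None:
            mu, sd = x.mean(axis=0), x.std(axis=0)
            sd[sd == 0] = 1.0
            if fit_norm:
                self._norm = (mu, sd)
        mu, sd = self._norm
        cd = (x - mu) / sd
        imaging = {}
        for source, cols in self.imaging_columns.items():
            if cols and all(c in cohort.columns for c in cols):
                m = cohort[cols].to_numpy(float)
                imaging[source] = (m - m.mean(axis=0)) / np.where(
                    m.std(axis=0) == 0, 1.0, m.std(axis=0))
        return cd, imaging

    def _chain_outputs(self, cd, imaging, context: DynamicContext | None,
                       rng=None, sample=False, as_tensor=False) -> dict:
        """Evaluate the tasks in order; returns per-task output (q or risk)."""
        ctx = context or DynamicContext()
        outputs: dict[str, object] = {}
        for spec in self.tasks:
            pred_vals = []
            for p in spec.predecessors:
                pspec = self.spec(p)
                up = outputs[p]
                if as_tensor:
                    # gradients keep flowing through non-substituted entries
                    pred_vals.append(_substitute_tensor(
                        pspec, ctx, up if isinstance(up, Tensor) else Tensor(up)))
                else:
                    up_np = up.data if isinstance(up, Tensor) else up
                    pred_vals.append(dynamic_input_value(
                        pspec, ctx.t_p, up_np,
                        labels=ctx.class_labels.get(p),
                        events=ctx.events.get(p), times=ctx.times.get(p)))
            x = assemble_inputs(spec, cd, imaging, pred_vals)
            model = self.models.get(spec.name)
            if model is None:
                raise ValueError(f"no model attached to task {spec.name!r}")
            out = model.forward(x if isinstance(x, Tensor) else Tensor(x),
                                rng=rng, sample=sample and model.bayesian)
            outputs[spec.name] = out if as_tensor else (
                out.data if isinstance(out, Tensor) else out)
        return outputs

    # -- training ------------------------------------------------------------
    def fit(self, cohort: pd.DataFrame, epochs: int = 300, lr: float = 0.05,
            seed: int = 0, beta: float = 1.0,
            dynamic_times: tuple = (12.0, 24.0, 60.0),
            dynamic_fraction: float = 0.5, verbose: bool = False):
        """Jointly optimize all task models on a learning cohort.

        Total loss is the unweighted sum of per-task losses (weighted
        BCE for the classification task, NPLL per survival task) plus
        the KL term scaled by 1/n when any model is Bayesian.  Patients
        with a missing outcome are masked out of that task's loss only.
        After fitting, each survival task's Breslow baseline is
        computed on the training data.

        A fraction of the epochs (`dynamic_fraction`, when any task has
        predecessors and `dynamic_times` is nonempty) is trained at a
        randomly drawn positive prognosis time, substituting the
        training patients' known outcomes into the predecessor inputs.
        This outcome substitution during training calibrates the
        finite +-C stand-ins, which a model trained only at t_p = 0
        never observes (its predecessor channels can even be collinear
        with the clinical features); without it dynamic predictions are
        not reliably better than static ones.
        """
        from .autodiff import Adam

        cd, imaging = self._design(cohort, fit_norm=True)
        n = len(cohort)
        rng = np.random.default_rng(seed)
        has_preds = any(t.predecessors for t in self.tasks)
        contexts = {0.0: DynamicContext()}
        if has_preds and dynamic_fraction > 0:
            for t_p in dynamic_times:
                contexts[t_p] = context_from_cohort(cohort, t_p)
        params = [p for m in self.models.values() for p in m.parameters()]
        opt = Adam(params, lr=lr)
        any_bayes = any(m.bayesian for m in self.models.values())

        task_data = {}
        for spec in self.tasks:
            if spec.kind == "classification":
                labels = cohort[f"{spec.name}_label"].to_numpy(float)
                valid = ~np.isnan(labels)
                stats = BatchClassStats.from_labels(labels[valid])
                self.class_stats[spec.name] = stats
                task_data[spec.name] = (valid, labels, stats)
            else:
                ev = cohort[f"{spec.name}_event"].to_numpy(float)
                tm = cohort[f"{spec.name}_time"].to_numpy(float)
                valid = ~np.isnan(ev)
                if not np.any(ev[valid] == 1):
                    raise ValueError(f"task {spec.name!r} has no events in training data")
                task_data[spec.name] = (valid, ev, tm)

        log = []
        t_choices = sorted(contexts)
        for epoch in range(epochs):
            opt.zero_grad()
            if len(t_choices) > 1 and rng.uniform() < dynamic_fraction:
                t_p = t_choices[rng.integers(1, len(t_choices))]
            else:
                t_p = 0.0
            outputs = self._chain_outputs(cd, imaging, contexts[t_p], rng=rng,
                                          sample=any_bayes, as_tensor=True)
            total = None
            entry = {"epoch": epoch}
            for spec in self.tasks:
                out = outputs[spec.name]
                if spec.kind == "classification":
                    valid, labels, stats = task_data[spec.name]
                    idx = np.flatnonzero(valid)
                    loss = weighted_bce(F.sigmoid(out[idx]), labels[idx], stats)
                else:
                    valid, ev, tm = task_data[spec.name]
                    idx = np.flatnonzero(valid)
                    loss = npll(out[idx], ev[idx].astype(bool), tm[idx])
                entry[spec.name] = loss.item()
                total = loss if total is None else total + loss
            if any_bayes:
                kl = None
                for m in self.models.values():
                    k = m.kl()
                    kl = k if kl is None else kl + k
                total = total + beta * kl / float(n)
                entry["kl"] = kl.item() if isinstance(kl, Tensor) else float(kl)
            entry["total"] = total.item()
            log.append(entry)
            total.backward()
            opt.step()
            if verbose and epoch % 50 == 0:
                print(f"epoch {epoch}: total {entry['total']:.4f}")

        # Breslow baselines from the fitted (mean) risks
        final = self._chain_outputs(cd, imaging, None, sample=False)
        for spec in self.tasks:
            if spec.kind == "survival":
                valid, ev, tm = task_data[spec.name]
                idx = np.flatnonzero(valid)
                self.baselines[spec.name] = breslow(
                    np.asarray(final[spec.name])[idx], ev[idx].astype(bool), tm[idx])
        return pd.DataFrame(log)

    # -- inference -----------------------------------------------------------
    def predict_risks(self, cohort: pd.DataFrame, t_p: float = 0.0,
                      context: DynamicContext | None = None) -> pd.DataFrame:
        """Per-task model outputs as a tidy frame (mean / deterministic pass).

        Classification tasks yield `<task>_q` and `<task>_prob`;
        survival tasks yield `<task>_risk`.
        """
        if context is None:
            context = context_from_cohort(cohort, t_p) if t_p > 0 else DynamicContext()
        cd, imaging = self._design(cohort)
        outputs = self._chain_outputs(cd, imaging, context, sample=False)
        cols = {}
        for spec in self.tasks:
            out = np.asarray(outputs[spec.name], float)
            if spec.kind == "classification":
                cols[f"{spec.name}_q"] = out
                cols[f"{spec.name}_prob"] = 1.0 / (1.0 + np.exp(-out))
            else:
                cols[f"{spec.name}_risk"] = out
        return pd.DataFrame(cols, index=cohort.index)

    def forward(self, cohort: pd.DataFrame, t_p: float = 0.0,
                context: DynamicContext | None = None, K: int = 0,
                seed: int = 0, time_grid=None) -> list[dict]:
        """Full prediction bundles, one dict per patient.

        Each bundle maps task name to value (probability or risk), the
        survival curve where a Breslow baseline is available, the
        posterior-predictive std when `K` >= 2 and the model is
        Bayesian, and the risk-group label when thresholds are set.
        """
        risks = self.predict_risks(cohort, t_p=t_p, context=context)
        if context is None:
            context = context_from_cohort(cohort, t_p) if t_p > 0 else DynamicContext()
        stds = {}
        if K >= 2 and any(m.bayesian for m in self.models.values()):
            rng = np.random.default_rng(seed)
            cd, imaging = self._design(cohort)
            draws = {t.name: [] for t in self.tasks}
            for _ in range(K):
                outs = self._chain_outputs(cd, imaging, context, rng=rng,
                                           sample=True)
                for name, o in outs.items():
                    draws[name].append(np.asarray(o, float))
            stds = {name: np.stack(v).std(axis=0) for name, v in draws.items()}

        bundles = []
        for i in range(len(cohort)):
            bundle = {}
            for spec in self.tasks:
                name = spec.name
                if spec.kind == "classification":
                    prob = risks[f"{name}_prob"].iloc[i]
                    entry = {"value": prob, "q": risks[f"{name}_q"].iloc[i],
                             "risk_group": int(prob > 0.5)}
                else:
                    r = risks[f"{name}_risk"].iloc[i]
                    entry = {"value": r, "risk": r}
                    if name in self.baselines:
                        entry["survival_curve"] = survival_curve(
                            r, self.baselines[name], time_grid)
                    if name in self.thresholds:
                        entry["risk_group"] = int(r > self.thresholds[name])
                if name in stds:
                    entry["std"] = float(stds[name][i])
                bundle[name] = entry
            bundles.append(bundle)
        return bundles

    def dynamic_predict(self, cohort: pd.DataFrame, context: DynamicContext,
                        **kwargs) -> pd.DataFrame:
        """Predictions refined by the outcomes known at context.t_p."""
        return self.predict_risks(cohort, t_p=context.t_p, context=context)
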