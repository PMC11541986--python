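"""Sequential network: input assembly, dynamic substitution, joint training."""

import numpy as np
import pandas as pd
import pytest

from seqprog.sequential_network import (CLASS_SUBSTITUTION, SURV_SUBSTITUTION,
                                        DynamicContext, SequenceGraph,
                                        TaskSpec, assemble_inputs,
                                        context_from_cohort,
                                        dynamic_input_value)
from seqprog.synthetic_cohort import CohortConfig, generate_cohort

RNG = np.random.default_rng(17)


class TestTaskSpecAndGraph:
    def test_clinical_data_is_mandatory(self):
        with pytest.raises(ValueError, match="mandatory"):
            TaskSpec("lni", "classification", input_sources=("HCR",))

    def test_predecessors_must_be_earlier(self):
        with pytest.raises(ValueError):
            SequenceGraph([
                TaskSpec("lni", "classification", predecessors=("bcr",)),
                TaskSpec("bcr", "survival"),
            ])

    def test_canonical_order_enforced(self):
        with pytest.raises(ValueError, match="order"):
            SequenceGraph([TaskSpec("bcr", "survival"),
                           TaskSpec("lni", "classification")])

    def test_default_graph_is_a_full_chain(self):
        g = SequenceGraph.default()
        names = [t.name for t in g.tasks]
        assert names == ["lni", "bcr", "mfs", "dadt", "crpc", "pcss"]
        assert g.tasks[-1].predecessors == tuple(names[:-1])

    def test_imaging_graph_input_dimensions(self):
        g = SequenceGraph.default_imaging()
        # LNI: 6 CD + 6 HCR = 12; BCR: 6 CD + 6 DLR + 1 predecessor = 13
        assert g.input_dim(g.spec("lni")) == 12
        assert g.input_dim(g.spec("bcr")) == 13
        assert g.input_dim(g.spec("mfs")) == 8


class TestAssembleInputs:
    def test_concatenation_order_and_width(self):
        spec = TaskSpec("mfs", "survival", predecessors=("lni", "bcr"))
        cd = RNG.normal(size=(4, 6))
        out = assemble_inputs(spec, cd, {}, [np.ones(4), np.zeros(4)])
        assert out.shape == (4, 8)
        assert np.allclose(out[:, :6], cd)
        assert np.allclose(out[:, 6], 1.0)
        assert np.allclose(out[:, 7], 0.0)

    def test_missing_imaging_source_raises(self):
        spec = TaskSpec("lni", "classification", input_sources=("CD", "HCR"))
        with pytest.raises(ValueError, match="HCR"):
            assemble_inputs(spec, np.zeros((2, 6)), {}, [])

    def test_unresolved_predecessor_raises(self):
        spec = TaskSpec("mfs", "survival", predecessors=("bcr",))
        with pytest.raises(ValueError, match="unresolved"):
            assemble_inputs(spec, np.zeros((2, 6)), {}, [None])


class TestDynamicInputValue:
    def test_classification_substitutions(self):
        spec = TaskSpec("lni", "classification")
        up = np.array([0.3, -0.2])
        assert np.allclose(
            dynamic_input_value(spec, 12.0, up, labels=np.array([1.0, 0.0])),
            [CLASS_SUBSTITUTION, -CLASS_SUBSTITUTION])

    def test_survival_substitution_for_observed_event(self):
        spec = TaskSpec("bcr", "survival")
        out = dynamic_input_value(spec, 24.0, np.array([0.5, 0.5]),
                                  events=np.array([1.0, 1.0]),
                                  times=np.array([10.0, 30.0]))
        assert out[0] == SURV_SUBSTITUTION     # event before t_p
        assert out[1] == 0.5                   # event after t_p: model value

    def test_time_zero_passes_model_value_through(self):
        spec = TaskSpec("lni", "classification")
        up = np.array([1.23])
        assert dynamic_input_value(spec, 0.0, up, labels=np.array([1.0]))[0] == 1.23

    def test_unknown_label_falls_back_to_model(self):
        spec = TaskSpec("lni", "classification")
        out = dynamic_input_value(spec, 12.0, np.array([0.7]),
                                  labels=np.array([np.nan]))
        assert out[0] == 0.7

    def test_context_rejects_event_after_prognosis_time(self):
        with pytest.raises(ValueError, match="after t_p"):
            DynamicContext(t_p=12.0, events={"bcr": np.array([1.0])},
                           times={"bcr": np.array([20.0])})


@pytest.fixture(scope="module")
def trained_graph():
    df, _ = generate_cohort(CohortConfig(n_patients=400, seed=21))
    graph = SequenceGraph.default().build_models(hidden_layers=(), seed=1)
    graph.fit(df, epochs=150, lr=0.05, seed=1)
    return graph, df


class TestForwardAndDynamics:
    def test_zero_weight_models(self, cohort_small):
        df, _ = cohort_small
        g = SequenceGraph.default().build_models(hidden_layers=(), seed=0)
        for m in g.models.values():
            for p in m.parameters():
                p.data[...] = 0.0
        g._design(df, fit_norm=True)
        preds = g.predict_risks(df)
        assert np.allclose(preds.lni_prob, 0.5)
        for task in ("bcr", "mfs", "dadt", "crpc", "pcss"):
            assert np.allclose(preds[f"{task}_risk"], 0.0)

    def test_empty_context_equals_static_forward(self, trained_graph):
        graph, df = trained_graph
        static = graph.predict_risks(df.iloc[:30], t_p=0)
        dynamic = graph.dynamic_predict(df.iloc[:30], DynamicContext(t_p=0.0))
        pd.testing.assert_frame_equal(static, dynamic)

    def test_no_events_by_tp_means_only_label_substitution_changes(self, trained_graph):
        graph, df = trained_graph
        sub = df[(df.bcr_time > 24) | (df.bcr_event == 0)].iloc[:20]
        ctx = context_from_cohort(sub, 24.0)
        assert all((ctx.events[t] == 0).all() for t in ctx.events)

    def test_lni_prediction_constant_over_time(self, trained_graph):
        graph, df = trained_graph
        p0 = graph.predict_risks(df.iloc[:25], t_p=0)["lni_prob"]
        p24 = graph.predict_risks(df.iloc[:25], t_p=24)["lni_prob"]
        assert np.allclose(p0, p24)

    def test_known_bcr_event_substitutes_plus_ten_downstream(self, trained_graph):
        graph, df = trained_graph
        hit = df[(df.bcr_event == 1) & (df.bcr_time < 24)].iloc[:5]
        ctx = context_from_cohort(hit, 24.0)
        cd, imaging = graph._design(hit)
        spec = graph.spec("dadt")
        outputs = graph._chain_outputs(cd, imaging, ctx)
        vals = dynamic_input_value(graph.spec("bcr"), 24.0,
                                   np.asarray(outputs["bcr"]),
                                   events=ctx.events["bcr"],
                                   times=ctx.times["bcr"])
        assert np.allclose(vals, SURV_SUBSTITUTION)
        # and the downstream risks actually move
        r0 = graph.predict_risks(hit, t_p=0)["dadt_risk"]
        r24 = graph.predict_risks(hit, t_p=24)["dadt_risk"]
        assert not np.allclose(r0, r24)


class TestJointFit:
    def test_single_task_graph_reduces_to_standalone_training(self, cohort_small):
        from seqprog.autodiff import Adam, Tensor
        from seqprog.neural_core import MLP, MLPConfig
        from seqprog.survival_core import BatchClassStats, weighted_bce
        import seqprog.autodiff as F

        df, _ = cohort_small
        graph = SequenceGraph([TaskSpec("lni", "classification")])
        graph.build_models(hidden_layers=(), seed=3)
        log = graph.fit(df, epochs=40, lr=0.05, seed=3)

        # standalone replica with identical init and data handling
        model = MLP(MLPConfig(input_dim=6, hidden_layers=()), seed=3000)
        cd, _ = graph._design(df)
        labels = df.lni_label.to_numpy(float)
        stats = BatchClassStats.from_labels(labels)
        opt = Adam(model.parameters(), lr=0.05)
        losses = []
        for _ in range(40):
            opt.zero_grad()
            q = model.forward(Tensor(cd))
            loss = weighted_bce(F.sigmoid(q), labels, stats)
            losses.append(loss.item())
            loss.backward()
            opt.step()
        assert np.allclose(log["lni"].to_numpy(), losses, atol=1e-10)

    def test_deterministic_replay(self, cohort_small):
        df, _ = cohort_small
        runs = []
        for _ in range(2):
            g = SequenceGraph.default().build_models(hidden_layers=(), seed=5)
            g.fit(df, epochs=30, lr=0.05, seed=5)
            runs.append(np.concatenate([p.data.ravel()
                                        for m in g.models.values()
                                        for p in m.parameters()]))
        assert np.array_equal(runs[0], runs[1])

    def test_bayesian_graph_with_frozen_sigma_matches_deterministic_outputs(
            self, cohort_small):
        # the SN limit of the BSN: every posterior held at its mean
        df, _ = cohort_small
        det = SequenceGraph.default().build_models(hidden_layers=(), seed=2)
        bayes = SequenceGraph.default().build_models(hidden_layers=(),
                                                     bayesian=True, seed=2)
        for name, m in bayes.models.items():
            for lb, ld in zip(m.layers, det.models[name].layers):
                if hasattr(lb, "W") and hasattr(lb.W, "mu"):
                    lb.W.mu.data[...] = ld.W.data
                    lb.b.mu.data[...] = ld.b.data
        det._design(df, fit_norm=True)
        bayes._design(df, fit_norm=True)
        out_det = det._chain_outputs(*det._design(df), None, sample=False)
        out_bayes = bayes._chain_outputs(*bayes._design(df), None, sample=False)
        for task in out_det:
            assert np.array_equal(np.asarray(out_det[task]),
                                  np.asarray(out_bayes[task]))

    def test_missing_downstream_outcomes_are_masked_not_fatal(self, cohort_small):
        df, _ = cohort_small
        df = df.copy()
        df.loc[df.index[:40], "pcss_event"] = np.nan
        df.loc[df.index[:40], "pcss_time"] = np.nan
        g = SequenceGraph.default().build_models(hidden_layers=(), seed=0)
        log = g.fit(df, epochs=10, lr=0.05, seed=0)
        assert np.isfinite(log["pcss"]).all()

    def test_task_with_no_events_raises(self, cohort_small):
        df, _ = cohort_small
        df = df.copy()
        df["pcss_event"] = 0
        g = SequenceGraph.default().build_models(hidden_layers=(), seed=0)
        with pytest.raises(ValueError, match="no events"):
            g.fit(df, epochs=2, seed=0)

    def test_breslow_baselines_attached_after_fit(self, trained_graph):
        graph, df = trained_graph
        for task in ("bcr", "mfs", "dadt", "crpc", "pcss"):
            assert task in graph.baselines
        bundles = graph.forward(df.iloc[:2])
        curve = bundles[0]["bcr"]["survival_curve"]
        assert curve(0.0) == 1.0
        assert np.all(np.diff(curve.probabilities) <= 1e-12)
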