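"""Evaluation metrics against brute-force pair-enumeration oracles."""

import numpy as np
import pytest

from seqprog.metrics import (CensoringDistribution, auroc, balanced_accuracy,
                             concordance_index, concordance_index_ipcw,
                             cumulative_dynamic_auc, dice_similarity)
from conftest import random_survival_data

RNG = np.random.default_rng(123)


def brute_force_cindex(risks, events, times):
    """O(n^2) concordance: comparable iff y_i < y_j and event at i."""
    num = den = 0.0
    n = len(risks)
    for i in range(n):
        if not events[i]:
            continue
        for j in range(n):
            if times[i] < times[j]:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return num / den


class TestAUCAndBA:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_pair_counting_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])

    def test_balanced_accuracy_perfect(self):
        assert balanced_accuracy([0.9, 0.1], [1, 0]) == 1.0

    def test_all_positive_on_balanced_labels(self):
        assert balanced_accuracy([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.5

    def test_confusion_matrix_hand_count(self):
        ba = balanced_accuracy([0.9, 0.2, 0.6, 0.4], [1, 0, 0, 1])
        assert ba == pytest.approx(0.5)


class TestConcordance:
    def test_reverse_ordered_risks_no_censoring(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        risks = -times
        assert concordance_index(risks, np.ones(4, bool), times) == 1.0

    def test_equal_risks_give_half(self):
        assert concordance_index(np.zeros(5), np.ones(5, bool),
                                 np.arange(1.0, 6.0)) == 0.5

    def test_spec_style_small_example_follows_the_comparability_rule(self):
        # pairs (0,1) and (0,2) are the only comparable ones; both concordant
        times, events, risks = [2.0, 4.0, 6.0], [1, 0, 1], [3.0, 1.0, 2.0]
        assert concordance_index(risks, events, times) == pytest.approx(
            brute_force_cindex(risks, events, times)) == 1.0

    def test_matches_brute_force_on_random_instances(self):
        for _ in range(200):
            n = int(RNG.integers(3, 31))
            risks, events, times = random_survival_data(RNG, n)
            if not events.any():
                events[0] = True
            # occasional tied risks exercise the 1/2 rule
            if RNG.uniform() < 0.3:
                risks = np.round(risks)
            has_pairs = any(events[i] and times[i] < times[j]
                            for i in range(n) for j in range(n))
            if not has_pairs:
                continue
            assert concordance_index(risks, events, times) == pytest.approx(
                brute_force_cindex(risks, events, times), abs=1e-12)


def censoring_km(events, times):
    """Independent reversed Kaplan-Meier for G(t) (right-continuous)."""
    order = np.argsort(times)
    t_sorted = np.asarray(times)[order]
    cens = ~np.asarray(events, bool)[order]
    n = len(t_sorted)
    surv = 1.0
    steps = []
    for k in range(n):
        if cens[k]:
            surv *= 1.0 - 1.0 / (n - k)
            steps.append((t_sorted[k], surv))
    def G(t):
        out = 1.0
        for u, s in steps:
            if u <= t:
                out = s
        return out
    return G


def brute_force_cicw(risks, events, times, G, tau):
    num = den = 0.0
    n = len(risks)
    for i in range(n):
        if not events[i] or times[i] >= tau:
            continue
        w = G(times[i]) ** -2
        for j in range(n):
            if times[i] < times[j]:
                den += w
                if risks[i] > risks[j]:
                    num += w
                elif risks[i] == risks[j]:
                    num += 0.5 * w
    return num / den


class TestCICW:
    def test_no_censoring_equals_plain_concordance(self):
        risks = RNG.normal(size=12)
        times = RNG.exponential(5, 12) + 0.1
        events = np.ones(12, bool)
        ci = concordance_index(risks, events, times)
        cicw = concordance_index_ipcw(risks, events, times, events, times,
                                      tau=times.max())
        assert cicw == pytest.approx(ci, abs=1e-12)

    def test_equal_risks_give_half(self):
        risks, events, times = random_survival_data(RNG, 15)
        events[:3] = True
        cicw = concordance_index_ipcw(np.zeros(15), events, times, events, times)
        assert cicw == pytest.approx(0.5)

    def test_matches_double_loop_weighted_oracle(self):
        for _ in range(25):
            n = 6
            risks, events, times = random_survival_data(RNG, n, censor_frac=0.4)
            if events.sum() < 2:
                events[:2] = True
            tau = float(np.quantile(times, 0.8))
            if not ((events) & (times < tau)).any():
                continue
            G = censoring_km(events, times)
            ours = concordance_index_ipcw(risks, events, times, events, times,
                                          tau=tau)
            oracle = brute_force_cicw(risks, events, times, G, tau)
            assert ours == pytest.approx(oracle, abs=1e-10)


def brute_force_cda(risks, events, times, G, t):
    """IPCW cumulative/dynamic AUC at horizon t."""
    cases = [i for i in range(len(risks)) if times[i] <= t and events[i]]
    controls = [j for j in range(len(risks)) if times[j] > t]
    if not cases or not controls:
        return np.nan
    wnum = wden = 0.0
    for i in cases:
        w = 1.0 / G(times[i])
        for j in controls:
            wden += w
            if risks[i] > risks[j]:
                wnum += w
            elif risks[i] == risks[j]:
                wnum += 0.5 * w
    return wnum / wden


class TestCDA:
    def test_perfectly_ordered_risks_no_censoring(self):
        times = np.arange(1.0, 9.0)
        risks = -times
        events = np.ones(8, bool)
        grid = np.array([2.5, 4.5, 6.5])
        aucs, mean = cumulative_dynamic_auc(risks, events, times, events,
                                            times, grid)
        assert np.allclose(aucs, 1.0)
        assert mean == pytest.approx(1.0)

    def test_constant_risks(self):
        times = np.arange(1.0, 9.0)
        events = np.ones(8, bool)
        _, mean = cumulative_dynamic_auc(np.zeros(8), events, times, events,
                                         times, np.array([3.5]))
        assert mean == pytest.approx(0.5)

    def test_matches_brute_force_weighted_enumeration(self):
        for _ in range(25):
            n = 8
            risks, events, times = random_survival_data(RNG, n, censor_frac=0.3)
            if events.sum() < 2:
                events[:2] = True
            t = float(np.median(times)) + 0.01
            G = censoring_km(events, times)
            oracle = brute_force_cda(risks, events, times, G, t)
            if np.isnan(oracle):
                continue
            aucs, _ = cumulative_dynamic_auc(risks, events, times, events,
                                             times, np.array([t]))
            assert aucs[0] == pytest.approx(oracle, abs=1e-10)


class TestInvarianceAndDice:
    def test_metrics_invariant_to_monotone_risk_transforms(self):
        risks, events, times = random_survival_data(RNG, 40)
        events[:5] = True
        labels = (risks + RNG.normal(size=40) > 0).astype(int)
        scores = 1 / (1 + np.exp(-risks))
        transformed = np.exp(3 * risks) + 7
        assert auroc(scores, labels) == pytest.approx(
            auroc(np.exp(scores), labels))
        assert concordance_index(risks, events, times) == pytest.approx(
            concordance_index(transformed, events, times))
        tau = float(np.quantile(times, 0.8))
        assert concordance_index_ipcw(risks, events, times, events, times,
                                      tau=tau) == pytest.approx(
            concordance_index_ipcw(transformed, events, times, events, times,
                                   tau=tau))

    def test_censoring_distribution_starts_at_one_and_decreases(self):
        _, events, times = random_survival_data(RNG, 50, censor_frac=0.5)
        G = CensoringDistribution.fit(events, times)
        assert G(0.0) == 1.0
        vals = G(np.sort(times))
        assert np.all(np.diff(vals) <= 1e-12)

    @pytest.mark.parametrize("pred,truth,expected", [
        ("identical", None, 1.0), ("disjoint", None, 0.0), ("half", None, 0.5),
    ])
    def test_dice_similarity(self, pred, truth, expected):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        if pred == "identical":
            a[0] = b[0] = True
        elif pred == "disjoint":
            a[0, 0, 0] = True
            b[2, 2, 2] = True
        else:
            a[0, 0, :2] = True       # |A| = 2
            b[0, :2, 0] = True       # |B| = 2, overlap 1
        assert dice_similarity(a, b) == expected

    def test_dice_empty_convention(self):
        z = np.zeros((2, 2, 2), bool)
        assert dice_similarity(z, z) == 1.0
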