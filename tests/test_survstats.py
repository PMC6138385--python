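import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

import prepvote as pv
from prepvote.survstats import (
    ConvergenceError,
    bh_adjust,
    compare_log2_hr_paired,
    confusion_metrics,
    cox_binary_hr,
    km_estimate,
    logrank_test,
    roc_auc,
)
from conftest import random_survival


# ---------------------------------------------------------------- oracles

def grid_search_breslow_beta(times, events, x, lo=-5.0, hi=5.0, step=1e-4):
    """Independent brute-force maximizer of the Breslow partial likelihood."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, int)
    betas = np.arange(lo, hi + step, step)
    ll = np.zeros_like(betas)
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n1 = int((at_risk & (x == 1)).sum())
        n0 = int((at_risk & (x == 0)).sum())
        ev = (times == t) & (events == 1)
        d = int(ev.sum())
        d1 = int((ev & (x == 1)).sum())
        ll += d1 * betas - d * np.log(n1 * np.exp(betas) + n0)
    return betas[np.argmax(ll)]


def hand_logrank(times, events, groups):
    """Exhaustive risk-table tabulation of the two-sample log-rank statistic."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    lvl = np.unique(groups)
    o1 = e1 = v = 0.0
    for t in sorted(set(times[events == 1])):
        n = (times >= t).sum()
        n1 = ((times >= t) & (groups == lvl[1])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == lvl[1])).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


def pair_counting_auc(probs, labels):
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def stepup_bh(pvals):
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


# ---------------------------------------------------------------- KM

class TestKaplanMeier:
    def test_single_event_example(self):
        curve = km_estimate([2, 3, 3, 3], [1, 0, 0, 0])
        assert curve.survival_at(1.9) == 1.0
        assert curve.survival_at(2.0) == pytest.approx(0.75)
        assert curve.survival_at(10.0) == pytest.approx(0.75)

    def test_no_events_flat_at_one(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(99.0) == 1.0

    def test_distinct_events_step_through_k_over_n(self):
        n = 6
        curve = km_estimate(np.arange(1, n + 1), np.ones(n, dtype=int))
        np.testing.assert_allclose(curve.survival, (n - np.arange(1, n + 1)) / n)

    def test_matches_lifelines(self, rng):
        times, events, _ = random_survival(rng, 60)
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert kmf.predict(t) == pytest.approx(s, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


# ---------------------------------------------------------------- log-rank

class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 0, 1, 1, 0]
        groups = [0, 0, 0, 1, 1, 1]
        stat, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_example(self):
        times = [1, 2, 3, 4]
        events = [1, 1, 1, 1]
        groups = [0, 0, 1, 1]
        stat, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(hand_logrank(times, events, groups))

    def test_matches_lifelines(self, rng):
        times, events, groups = random_survival(rng, 50)
        stat, p = logrank_test(times, events, groups)
        ref = ll_logrank(times[groups == 0], times[groups == 1],
                         events[groups == 0], events[groups == 1])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning, match="no events"):
            stat, p = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert (stat, p) == (0.0, 1.0)

    def test_wrong_group_count_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2], [1, 1], [0, 0])


# ---------------------------------------------------------------- Cox

class TestCoxBinary:
    def test_symmetric_groups_hr_one(self):
        fit = cox_binary_hr([1, 2, 1, 2], [1, 1, 1, 1], [0, 0, 1, 1])
        assert fit.hr == pytest.approx(1.0, abs=1e-6)

    def test_grid_oracle_on_worked_example(self):
        times, events, x = [1, 2, 3, 4], [1, 1, 1, 1], [1, 0, 1, 0]
        fit = cox_binary_hr(times, events, x)
        assert abs(fit.beta - grid_search_breslow_beta(times, events, x)) < 1e-3

    def test_monotone_likelihood_detected_and_matches_oracle_diagnosis(self):
        # all group-1 events precede every group-0 event: the partial
        # likelihood increases without bound, which the grid oracle shows as
        # an argmax pinned to its upper boundary
        times, events, x = [1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 0, 0]
        assert grid_search_breslow_beta(times, events, x) == pytest.approx(5.0)
        with pytest.raises(ConvergenceError, match="monotone"):
            cox_binary_hr(times, events, x)

    def test_grid_oracle_on_random_small_datasets(self, rng):
        for _ in range(50):
            times, events, x = random_survival(rng, int(rng.integers(4, 9)))
            fit = cox_binary_hr(times, events, x)
            assert abs(fit.beta - grid_search_breslow_beta(times, events, x)) < 1e-3

    def test_matches_lifelines_without_ties(self, rng):
        times, events, x = random_survival(rng, 80)
        df = pd.DataFrame({"t": times, "e": events, "x": x})
        cph = CoxPHFitter().fit(df, "t", "e")  # Efron = Breslow when tie-free
        fit = cox_binary_hr(times, events, x)
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-5)

    def test_large_sample_consistency(self):
        rng = np.random.default_rng(42)
        n = 2000
        x = rng.integers(0, 2, size=n)
        times = rng.exponential(1.0 / (0.1 * 2.0**x))
        fit = cox_binary_hr(times, np.ones(n, dtype=int), x)
        assert 1.8 <= fit.hr <= 2.2

    def test_separation_raises(self):
        with pytest.raises(ConvergenceError, match="separation"):
            cox_binary_hr([1, 2, 3, 4], [1, 1, 0, 0], [1, 1, 0, 0])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_binary_hr([1, 2], [0, 0], [0, 1])

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            cox_binary_hr([1, 2], [1, 1], [1, 1])

    def test_label_swap_inverts_hr_and_keeps_logrank(self, rng):
        for _ in range(5):
            times, events, x = random_survival(rng, 40)
            a = cox_binary_hr(times, events, x)
            b = cox_binary_hr(times, events, 1 - x)
            assert a.hr == pytest.approx(1.0 / b.hr, rel=1e-6)
            sa, _ = logrank_test(times, events, x)
            sb, _ = logrank_test(times, events, 1 - x)
            assert sa == pytest.approx(sb, rel=1e-10)

    def test_ci_ordering_invariant(self, rng):
        times, events, x = random_survival(rng, 30)
        fit = cox_binary_hr(times, events, x)
        assert fit.ci_low <= fit.hr <= fit.ci_high


# ---------------------------------------------------------------- BH

class TestBHAdjust:
    def test_worked_example(self):
        adjusted = bh_adjust([0.01, 0.04, 0.03, 0.002])
        np.testing.assert_allclose(adjusted, [0.02, 0.04, 0.04, 0.008])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_oracle_and_never_decreases(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 30)))
            adjusted = bh_adjust(p)
            np.testing.assert_allclose(adjusted, stepup_bh(p), atol=1e-12)
            assert (adjusted >= p - 1e-12).all()
            assert (adjusted <= 1.0).all()


# ---------------------------------------------------------------- ROC / confusion

class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0]).auc == 1.0

    def test_half_concordant_pairs(self):
        result = roc_auc([0.9, 0.4, 0.6, 0.1], [1, 0, 0, 1])
        assert result.auc == pytest.approx(0.5)
        assert result.auc == pytest.approx(
            pair_counting_auc([0.9, 0.4, 0.6, 0.1], [1, 0, 0, 1])
        )

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == pytest.approx(0.5)

    def test_pair_counting_oracle_random(self, rng):
        for _ in range(10):
            probs = rng.random(20)
            labels = rng.integers(0, 2, size=20)
            if labels.min() == labels.max():
                continue
            assert roc_auc(probs, labels).auc == pytest.approx(
                pair_counting_auc(probs, labels)
            )

    def test_monotone_transform_invariance(self, rng):
        probs = rng.random(30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[0], labels[1] = 0, 1
        base = roc_auc(probs, labels).auc
        assert roc_auc(np.exp(3 * probs), labels).auc == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestConfusion:
    def test_worked_example(self):
        m = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 1])
        assert (m.tp, m.fp, m.tn, m.fn) == (2, 0, 1, 1)
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.specificity == 1.0
        assert m.accuracy == 0.75

    def test_perfect_prediction(self):
        assert confusion_metrics([1, 0, 1], [1, 0, 1]).accuracy == 1.0

    def test_inverted_prediction(self):
        assert confusion_metrics([0, 1, 0], [1, 0, 1]).accuracy == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])


# ---------------------------------------------------------------- paired t

class TestPairedT:
    def test_identical_lists_degenerate(self):
        result = compare_log2_hr_paired([1.5, 2.0, 3.0], [1.5, 2.0, 3.0])
        assert result.degenerate

    def test_closed_form_example(self):
        log2_a = np.array([1.0, 1.5, 2.0])
        log2_b = np.array([0.8, 1.6, 1.7])
        result = compare_log2_hr_paired(2.0**log2_a, 2.0**log2_b)
        d = log2_a - log2_b
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert result.t == pytest.approx(expected_t)
        assert result.df == 2
        assert not result.degenerate

    def test_constant_shift_degenerate(self):
        a = np.array([1.0, 2.0, 4.0])
        result = compare_log2_hr_paired(a, a * 2.0)  # constant log2 offset
        assert result.degenerate

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            compare_log2_hr_paired([2.0], [1.0])
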