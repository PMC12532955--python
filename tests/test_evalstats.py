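"""Diagnostic metrics, exact binomial CIs, AUC, score statistics."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from methyldx.evalstats import (
    ConfusionCounts,
    auc_ci_bootstrap,
    auc_mann_whitney,
    clopper_pearson,
    compare_scores,
    confusion,
    correlation_auto,
    diagnostic_metrics,
    evaluate,
    quartile_correctness,
    round_half_up,
)


class TestConfusion:
    def test_all_correct(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_all_flipped(self):
        c = confusion([0, 0, 1, 1], [1, 1, 0, 0])
        assert (c.tp, c.tn) == (0, 0) and (c.fp, c.fn) == (2, 2)

    def test_manual_tally(self):
        c = confusion([1, 0, 1, 1, 0, 0], [1, 1, 0, 1, 0, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1], [1, 0])


class TestDiagnosticMetrics:
    def test_full_holdout_worked_example(self):
        """19/21 sensitivity and 22/25 specificity give 0.90/0.88/0.89 at 2 dp."""
        m = diagnostic_metrics(ConfusionCounts(tp=19, fp=3, tn=22, fn=2))
        assert round_half_up(m["sensitivity"]) == 0.90
        assert round_half_up(m["specificity"]) == 0.88
        assert round_half_up(m["balanced_accuracy"]) == 0.89

    def test_seronegative_subset_worked_example(self):
        m = diagnostic_metrics(ConfusionCounts(tp=5, fp=3, tn=11, fn=1))
        assert round_half_up(m["balanced_accuracy"]) == 0.81

    def test_likelihood_ratio_arithmetic(self):
        m = diagnostic_metrics(ConfusionCounts(tp=90, fp=12, tn=88, fn=10))
        assert m["lr_pos"] == pytest.approx(0.90 / 0.12)
        assert m["lr_neg"] == pytest.approx(0.10 / 0.88)

    def test_balanced_accuracy_identity_on_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(0, 50, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = diagnostic_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m["balanced_accuracy"] == (m["sensitivity"] + m["specificity"]) / 2

    def test_perfect_specificity_gives_infinite_lr(self):
        m = diagnostic_metrics(ConfusionCounts(tp=5, fp=0, tn=10, fn=0))
        assert np.isinf(m["lr_pos"])

    def test_empty_classes_raise(self):
        with pytest.raises(ValueError):
            diagnostic_metrics(ConfusionCounts(0, 0, 0, 0))


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x,n,lo,hi",
        [(19, 21, 0.70, 0.99), (22, 25, 0.69, 0.97), (5, 6, 0.36, 1.00),
         (11, 14, 0.49, 0.95), (14, 15, 0.68, 1.00)],
    )
    def test_reproduces_published_intervals(self, x, n, lo, hi):
        lower, upper = clopper_pearson(x, n)
        assert round_half_up(lower) == lo
        assert round_half_up(upper) == hi

    def test_boundaries_exact(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_matches_statsmodels_beta_method(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 100))
            x = int(rng.integers(0, n + 1))
            lo, hi = clopper_pearson(x, n)
            sm_lo, sm_hi = proportion_confint(x, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(sm_lo, abs=1e-12)
            assert hi == pytest.approx(sm_hi, abs=1e-12)

    def test_interval_contains_point_and_narrows_with_n(self):
        for k in (1, 2, 4, 8):
            lo, hi = clopper_pearson(3 * k, 10 * k)
            assert lo <= 0.3 <= hi
        widths = [np.diff(clopper_pearson(3 * k, 10 * k))[0] for k in (1, 2, 4, 8)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(1, 4, level=1.5)


class TestAuc:
    def test_perfect_and_uninformative(self):
        assert auc_mann_whitney([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc_mann_whitney([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5

    def test_tie_gets_half_credit(self):
        auc = auc_mann_whitney([0.9, 0.4, 0.4, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx((1 + 1 + 0.5 + 1) / 4)

    def test_equals_trapezoidal_roc_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(5, 100))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.uniform(size=n), 1)  # heavy ties
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([0.1, 0.9], [1, 1])


class TestAucBootstrap:
    def test_perfect_separation_degenerate_interval(self):
        lo, hi = auc_ci_bootstrap([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], n_boot=200)
        assert (lo, hi) == (1.0, 1.0)

    def test_same_seed_same_interval(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(size=40)
        y = rng.integers(0, 2, 40)
        y[:5], y[-5:] = 1, 0
        a = auc_ci_bootstrap(s, y, n_boot=2000, seed=9)
        b = auc_ci_bootstrap(s, y, n_boot=2000, seed=9)
        assert a == b

    def test_interval_covers_point_estimate(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 20 + [0] * 20)
        s = rng.uniform(size=40) + 0.3 * y
        lo, hi = auc_ci_bootstrap(s, y, n_boot=1000, seed=1)
        assert lo <= auc_mann_whitney(s, y) <= hi


class TestCompareScores:
    def test_identical_groups(self):
        s = np.array([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        t, p = compare_scores(s, [True, True, True, False, False, False],
                              [False, False, False, True, True, True])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a = np.array([2.1, 2.5, 1.9])
        b = np.array([1.0, 1.2, 0.8])
        s = np.concatenate([a, b])
        t, p = compare_scores(s, np.array([1, 1, 1, 0, 0, 0], bool),
                              np.array([0, 0, 0, 1, 1, 1], bool))
        sp = np.sqrt(((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4)
        t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand, abs=1e-10)

    def test_swapping_groups_flips_sign(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(size=10)
        ga = np.array([True] * 5 + [False] * 5)
        gb = ~ga
        t1, p1 = compare_scores(s, ga, gb)
        t2, p2 = compare_scores(s, gb, ga)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


class TestCorrelationAuto:
    def test_linear_gaussian_uses_pearson(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        y = 2 * x + 0.05 * rng.normal(size=100)
        method, r, p = correlation_auto(x, y)
        assert method == "pearson" and r > 0.99

    def test_monotone_heavy_tail_uses_spearman(self):
        rng = np.random.default_rng(7)
        x = rng.standard_cauchy(size=100)
        method, r, _ = correlation_auto(x, np.exp(np.clip(x, -20, 20)))
        assert method == "spearman" and r == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        x = np.linspace(0, 1, 50)
        _, r, _ = correlation_auto(x, -x + 0.0 * x**2)
        assert r == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlation_auto(np.ones(10), np.arange(10.0))


class TestQuartiles:
    def test_perfect_separation(self):
        s = [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1]
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        assert quartile_correctness(s, y, 0.5) == (1.0, 1.0)

    def test_everything_wrong(self):
        s = [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1]
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        assert quartile_correctness(s, y, 0.5) == (0.0, 0.0)

    def test_hand_built_mixed_case(self):
        s = [0.05, 0.15, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95]
        y = [0, 1, 0, 1, 0, 1, 1, 1]
        # n=8 -> quartile size 2; bottom {0.05, 0.15}: calls (0,0) vs (0,1) -> 0.5
        # top {0.85, 0.95}: calls (1,1) vs (1,1) -> 1.0
        assert quartile_correctness(s, y, 0.5) == (0.5, 1.0)


def test_evaluate_report_is_complete_and_consistent():
    rng = np.random.default_rng(8)
    y = np.array([1] * 21 + [0] * 25)
    s = np.clip(0.5 + 0.25 * (2 * y - 1) + rng.normal(0, 0.18, 46), 0.01, 0.99)
    groups = np.where(y == 1, "ra_seropos", "healthy")
    rep = evaluate(s, y, cutoff=0.52, group_labels=groups, n_boot=300, seed=0)
    assert rep["n_case"] == 21 and rep["n_control"] == 25
    assert rep["balanced_accuracy"]["value"] == pytest.approx(
        (rep["sensitivity"]["value"] + rep["specificity"]["value"]) / 2
    )
    counts = rep["counts"]
    assert counts["tp"] + counts["fn"] == 21
    assert rep["sensitivity"]["ci"] == list(clopper_pearson(counts["tp"], 21))
    assert set(rep["per_group_scores"]) == {"ra_seropos", "healthy"}
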