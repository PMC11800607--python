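"""Metrics and the replicate-comparison machinery."""

import numpy as np
import pytest
from scipy import stats as sps

from dtitwins.stats import (MetricsReport, benjamini_hochberg,
                            classification_report, compare_models, mae,
                            pearson, pr_auc, roc_auc, welch_t_test)


def pair_counting_auc(labels, scores):
    """Brute-force Mann-Whitney: fraction of correctly ordered pos/neg
    pairs, ties worth one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_and_inverted(self):
        assert roc_auc([0, 1], [0.1, 0.9]) == 1.0
        assert roc_auc([1, 0], [0.1, 0.9]) == 0.0

    def test_hand_counted_pairs(self):
        assert roc_auc([0, 1, 0, 1], [0.2, 0.3, 0.4, 0.5]) == 0.75

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # induce ties
            assert np.isclose(roc_auc(labels, scores),
                              pair_counting_auc(labels, scores))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.1, 0.9])


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_prevalence(self):
        labels = [0, 1, 0, 0, 1]
        assert np.isclose(pr_auc(labels, [0.5] * 5), 0.4)

    def test_step_sum_by_hand(self):
        assert np.isclose(pr_auc([0, 1, 1], [0.9, 0.8, 0.7]),
                          0.5 * 0.5 + 0.5 * (2 / 3))

    def test_no_positives_raises(self):
        with pytest.raises(ValueError):
            pr_auc([0, 0], [0.1, 0.2])


class TestWelch:
    def test_identical_samples(self):
        t, _, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_closed_form_example(self):
        t, df, _ = welch_t_test([1, 2, 3], [4, 5, 6])
        assert np.isclose(t, -3.6742, atol=1e-4)
        assert np.isclose(df, 4.0)

    def test_equal_variance_equal_size_df(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=6)
        y = x + 1.0  # identical variance
        _, df, _ = welch_t_test(x, y)
        assert np.isclose(df, 10.0)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            x = rng.normal(size=int(rng.integers(3, 20)))
            y = rng.normal(1, 2, size=int(rng.integers(3, 20)))
            t, df, p = welch_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert abs(t - ref.statistic) <= 1e-8
            assert abs(p - ref.pvalue) <= 1e-8

    def test_both_constant_equal_means_vacuous(self):
        t, _, p = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_degenerate_sizes(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1, 2, 3])


class TestBenjaminiHochberg:
    def test_single_p_reduces_to_raw_threshold(self):
        reject, _ = benjamini_hochberg([0.04], alpha=0.05)
        assert reject.tolist() == [True]

    def test_step_up_rejects_all_four(self):
        reject, _ = benjamini_hochberg([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert reject.all()

    def test_all_ones_rejects_none(self):
        reject, _ = benjamini_hochberg([1.0, 1.0, 1.0], alpha=0.05)
        assert not reject.any()

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        pvals = rng.random(20)
        prev = np.zeros(20, dtype=bool)
        for alpha in (0.01, 0.05, 0.1, 0.3):
            reject, _ = benjamini_hochberg(pvals, alpha)
            assert (prev <= reject).all()
            prev = reject

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5], alpha=1.5)


def _replicates(model, values):
    return [MetricsReport(model, i, {"roc_auc": v, "pr_auc": v})
            for i, v in enumerate(values)]


class TestCompareModels:
    def test_dominant_model_flagged(self):
        reports = _replicates("a", [0.95, 0.951, 0.949, 0.95, 0.952]) \
            + _replicates("b", [0.80, 0.801, 0.799, 0.80, 0.802])
        table = compare_models(reports, alpha=0.001)
        assert (table["winner"] == "a").all()

    def test_identical_models_no_winner(self):
        values = [0.9, 0.91, 0.89, 0.9, 0.9]
        table = compare_models(_replicates("a", values)
                               + _replicates("b", values), alpha=0.001)
        assert (table["winner"] == "").all()

    def test_single_comparison_equals_raw_test(self):
        x, y = [0.9, 0.91, 0.92], [0.5, 0.52, 0.51]
        reports = [MetricsReport("a", i, {"roc_auc": v}) for i, v in enumerate(x)]
        reports += [MetricsReport("b", i, {"roc_auc": v}) for i, v in enumerate(y)]
        table = compare_models(reports, alpha=0.05)
        _, _, raw_p = welch_t_test(x, y)
        assert np.isclose(table["p"].iloc[0], raw_p)
        assert np.isclose(table["p_adj"].iloc[0], raw_p)

    def test_mae_winner_is_minimum(self):
        reports = [MetricsReport("a", i, {"mae": v})
                   for i, v in enumerate([0.1, 0.11, 0.09])]
        reports += [MetricsReport("b", i, {"mae": v})
                    for i, v in enumerate([0.5, 0.51, 0.49])]
        table = compare_models(reports, alpha=0.05)
        assert (table["winner"] == "a").all()

    def test_mismatched_metrics_raise(self):
        reports = [MetricsReport("a", 0, {"roc_auc": 0.9}),
                   MetricsReport("a", 1, {"pr_auc": 0.9}),
                   MetricsReport("b", 0, {"roc_auc": 0.8}),
                   MetricsReport("b", 1, {"roc_auc": 0.8})]
        with pytest.raises(ValueError):
            compare_models(reports)

    def test_classification_report_contents(self):
        report = classification_report("m", 0, [0, 1, 0, 1],
                                       [0.1, 0.9, 0.2, 0.8])
        assert report.metrics["roc_auc"] == 1.0
        assert report.metrics["pr_auc"] == 1.0


def test_regression_helpers():
    y = np.array([1.0, 2.0, 3.0])
    assert pearson(y, 2 * y) == pytest.approx(1.0)
    assert mae(y, y + 0.5) == pytest.approx(0.5)
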