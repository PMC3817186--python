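"""LOOCV ROC analysis, AUC comparison tests, and clinical count statistics."""

import numpy as np
import pandas as pd
import pytest

from dermcadx.cli import packaged_clinical_counts
from dermcadx.evaluation import (
    ConfusionCounts,
    UndefinedMetricError,
    auc,
    confusion_stats,
    delong_test,
    group_accuracy,
    loocv_scores,
    operating_point,
    paired_bootstrap_az,
    roc_result,
    univariate_az,
)
from dermcadx.selection import LabeledFeatureTable
from dermcadx.synthetic import generate_feature_table


def brute_force_auc(scores, labels):
    """All cross-class pairs, ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_hand_examples(self):
        assert auc([1, 2], [0, 1]) == 1.0
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5
        assert auc([3, 1, 2, 4], [0, 0, 1, 1]) == 0.75  # wins 3 of 4 pairs, one loss

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(4, 30)
            y = np.r_[0, 1, rng.integers(0, 2, n - 2)]  # both classes guaranteed
            s = rng.integers(0, 8, n).astype(float)  # many ties
            assert auc(s, y) == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        assert auc(np.exp(s), y) == pytest.approx(auc(s, y), abs=1e-12)
        assert auc(3 * s + 10, y) == pytest.approx(auc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auc([1.0, 2.0], [1, 1])


class TestLoocv:
    def test_separated_classes_near_perfect_az(self):
        table = generate_feature_table(
            30, 30, seed=5, mode="direct",
            informative_features=["shape.compactness"], effect_size=4.0,
        ).subset(["shape.compactness", "shape.asymmetry"])
        scores = loocv_scores(table)
        assert auc(scores, table.labels) >= 0.95

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(5)
        table = generate_feature_table(
            30, 30, seed=5, mode="direct", effect_size=3.0,
        ).subset(["shape.compactness", "shape.asymmetry"])
        permuted = LabeledFeatureTable(
            table.features, rng.permutation(table.labels), table.ids
        )
        scores = loocv_scores(permuted)
        assert 0.35 <= auc(scores, permuted.labels) <= 0.65

    def test_minimal_n_three(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        table = LabeledFeatureTable(X, np.array([0, 0, 1]))
        with pytest.raises(UndefinedMetricError, match="fold"):
            loocv_scores(table)  # removing the malignant record empties its class
        X4 = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0]})
        scores = loocv_scores(LabeledFeatureTable(X4, np.array([0, 0, 1, 1])))
        assert len(scores) == 4


class TestDelong:
    def test_self_comparison_is_null(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.normal(size=30)
        az_a, az_b, z, p = delong_test(s, s, y)
        assert az_a == az_b and z == 0.0 and p == 1.0

    def test_monotone_transform_gives_identical_az(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.normal(size=40)
        az_a, az_b, z, p = delong_test(s, 2 * s + 7, y)
        assert az_a == az_b and p == 1.0

    def test_variance_close_to_jackknife_oracle(self, rng):
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        a = rng.normal(size=40) + 0.8 * y
        b = rng.normal(size=40) + 0.5 * y
        az_a, az_b, z, _ = delong_test(a, b, y)
        var_delong = ((az_a - az_b) / z) ** 2
        # leave-one-out jackknife of the paired Az difference
        n = len(y)
        pseudo = []
        for i in range(n):
            keep = np.arange(n) != i
            d_i = auc(a[keep], y[keep]) - auc(b[keep], y[keep])
            pseudo.append(d_i)
        pseudo = np.asarray(pseudo)
        var_jack = (n - 1) / n * ((pseudo - pseudo.mean()) ** 2).sum()
        assert var_delong == pytest.approx(var_jack, rel=0.15)

    def test_detects_clear_separation_difference(self, rng):
        y = np.r_[np.zeros(60, int), np.ones(60, int)]
        good = rng.normal(size=120) + 3.0 * y
        junk = rng.normal(size=120)
        *_, p = delong_test(good, junk, y)
        assert p < 0.01


class TestPairedBootstrap:
    def test_identical_scores_degenerate_p_one(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.normal(size=40)
        assert paired_bootstrap_az(s, s, y, B=200, seed=0) == 1.0

    def test_power_against_a_real_az_gap(self):
        detections = 0
        for outer in range(20):
            rng = np.random.default_rng(100 + outer)
            y = np.r_[np.zeros(75, int), np.ones(75, int)]
            a = rng.normal(size=150) + 2.2 * y
            b = rng.normal(size=150) + 0.9 * y
            p = paired_bootstrap_az(a, b, y, B=500, seed=outer)
            detections += p < 0.05
        assert detections >= 19

    def test_type_one_error_within_binomial_bounds(self):
        rejections = 0
        for outer in range(100):
            rng = np.random.default_rng(3000 + outer)
            y = np.r_[np.zeros(40, int), np.ones(40, int)]
            a = rng.normal(size=80) + 1.0 * y
            b = rng.normal(size=80) + 1.0 * y
            p = paired_bootstrap_az(a, b, y, B=500, seed=outer)
            rejections += p < 0.05
        assert 1 <= rejections <= 11


class TestOperatingPoint:
    def test_perfect_separation_full_accuracy(self):
        roc = roc_result(np.array([1.0, 2.0, 8.0, 9.0]), np.array([0, 0, 1, 1]))
        op = operating_point(roc)
        assert op["accuracy"] == 1.0 and op["sensitivity"] == 1.0

    def test_enumerated_threshold_intervals(self):
        roc = roc_result(np.array([3.0, 1.0, 2.0, 4.0]), np.array([0, 0, 1, 1]))
        op = operating_point(roc)
        assert op["accuracy"] == 0.75
        assert op["specificity"] == 1.0  # accuracy tie resolved toward specificity

    def test_threshold_below_all_scores(self):
        roc = roc_result(np.array([3.0, 1.0, 2.0, 4.0]), np.array([0, 0, 1, 1]))
        op = operating_point(roc, mode="fixed-threshold", threshold=-100.0)
        assert op["sensitivity"] == 1.0 and op["specificity"] == 0.0

    def test_unattainable_sensitivity_target_flagged(self):
        roc = roc_result(np.array([1.0, 2.0, 2.0, 1.0]), np.array([0, 0, 1, 1]))
        op = operating_point(roc, mode="sensitivity-target", sensitivity_target=1.0)
        assert op["attained"] in (True, False)  # all thresholds enumerated
        ok = operating_point(roc, mode="sensitivity-target", sensitivity_target=0.5)
        assert ok["attained"]


class TestUnivariateAz:
    def test_orientation_free_range(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        X = pd.DataFrame(
            {"up": y + rng.normal(0, 0.5, 60), "down": -y + rng.normal(0, 0.5, 60)}
        )
        az = univariate_az(LabeledFeatureTable(X, y))
        assert (az >= 0.5).all() and (az <= 1.0).all()
        assert az["up"] > 0.8 and az["down"] > 0.8


class TestClinicalCounts:
    def test_dermatologist_overall_performance(self):
        counts = ConfusionCounts.from_csv(packaged_clinical_counts(), rater="dermatologist")
        s = confusion_stats(counts)
        assert round(s["sensitivity"] * 100, 2) == 83.33  # 145/174
        assert round(s["specificity"] * 100, 2) == 85.88  # 511/595
        assert round(s["accuracy"] * 100, 2) == 85.31     # 656/769
        # published 95% CI for sensitivity: 77.09-88.14%
        lo, hi = s["sensitivity_ci"]
        assert round(lo * 100, 2) == pytest.approx(77.09, abs=0.02)
        assert round(hi * 100, 2) == pytest.approx(88.14, abs=0.02)

    def test_cadx_operating_point_performance(self):
        counts = ConfusionCounts.from_csv(packaged_clinical_counts(), rater="cadx")
        s = confusion_stats(counts)
        assert round(s["sensitivity"] * 100, 2) == 85.63  # 149/174
        assert s["specificity"] == pytest.approx(521 / 595)

    def test_cadx_grouped_accuracy(self):
        counts = ConfusionCounts.from_csv(packaged_clinical_counts(), rater="cadx")
        acc = group_accuracy(counts)
        assert round(acc["melanocytic"] * 100, 2) == 91.38      # 350/383
        assert round(acc["non_melanocytic"] * 100, 2) == 82.90  # 320/386

    def test_all_correct_ci_reaches_one(self):
        t = pd.DataFrame(
            {
                "category": ["a", "b"],
                "class": ["benign", "malignant"],
                "n_correct": [10, 10],
                "n_incorrect": [0, 0],
            }
        )
        s = confusion_stats(ConfusionCounts(t))
        assert s["sensitivity"] == s["specificity"] == s["accuracy"] == 1.0
        assert s["accuracy_ci"][1] == pytest.approx(1.0)

    def test_single_group_equals_overall(self):
        counts = ConfusionCounts.from_csv(packaged_clinical_counts(), rater="cadx")
        acc = group_accuracy(counts, grouping={c: "all" for c in counts.table["category"]})
        assert acc["all"] == pytest.approx(670 / 769)

    def test_unmapped_category_rejected(self):
        counts = ConfusionCounts.from_csv(packaged_clinical_counts(), rater="cadx")
        with pytest.raises(ValueError, match="unmapped"):
            group_accuracy(counts, grouping={"bcc": "x"})
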