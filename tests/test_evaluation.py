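import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score

from accpulse import (
    chi_square_prop,
    compare_auc,
    confusion_metrics,
    evaluate_feature,
    pearson_r,
    roc_auc,
    students_t,
)
from accpulse.exceptions import DegenerateInputError, ShapeError
from accpulse.io import FeatureTable


def brute_auc(scores, labels):
    """Concordant-pair counting oracle (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == "PR"]
    neg = scores[labels == "PEA"]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 10, 11], ["PEA", "PEA", "PR", "PR"]) == 1.0

    def test_small_example(self):
        assert roc_auc([1, 2, 3, 4], ["PEA", "PR", "PEA", "PR"]) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_and_sklearn(self, seed):
        r = np.random.default_rng(seed)
        n = 30
        scores = np.round(r.standard_normal(n), 1)  # rounding forces ties
        labels = np.where(r.uniform(size=n) < 0.4, "PR", "PEA")
        if len(set(labels)) < 2:
            labels[:2] = ["PR", "PEA"]
        auc = roc_auc(scores, labels)
        assert auc == pytest.approx(brute_auc(scores, labels), abs=1e-12)
        assert auc == pytest.approx(
            roc_auc_score((labels == "PR").astype(int), scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(40)
        labels = np.where(rng.uniform(size=40) < 0.5, "PR", "PEA")
        labels[:2] = ["PR", "PEA"]
        a1 = roc_auc(scores, labels)
        a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_permutation_null_centres_on_half(self):
        r = np.random.default_rng(0)
        scores = r.standard_normal(30)
        labels = np.array(["PR"] * 10 + ["PEA"] * 20)
        aucs = []
        for _ in range(400):
            r.shuffle(labels)
            aucs.append(roc_auc(scores, labels))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([1.0, 2.0], ["PR", "PR"])


class TestConfusionMetrics:
    def test_consistent_integer_realization(self):
        # 31 PR / 79 PEA with tp=29, fn=2, tn=77, fp=2
        labels = np.array(["PR"] * 31 + ["PEA"] * 79)
        decisions = np.array(
            ["pulse_present"] * 29 + ["pulse_absent"] * 2
            + ["pulse_absent"] * 77 + ["pulse_present"] * 2
        )
        rep = confusion_metrics(decisions, labels)
        assert rep.sensitivity == pytest.approx(0.935, abs=5e-4)
        assert rep.specificity == pytest.approx(0.975, abs=5e-4)
        assert rep.accuracy == pytest.approx(0.964, abs=5e-4)
        assert (rep.tp + rep.fn, rep.tn + rep.fp) == (31, 79)

    def test_all_correct(self):
        labels = np.array(["PR", "PEA", "PR", "PEA"])
        decisions = np.where(labels == "PR", "pulse_present", "pulse_absent")
        rep = confusion_metrics(decisions, labels)
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0

    def test_all_absent(self):
        labels = np.array(["PR", "PEA", "PEA"])
        rep = confusion_metrics(["pulse_absent"] * 3, labels)
        assert rep.sensitivity == 0.0
        assert rep.specificity == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ShapeError):
            confusion_metrics(["pulse_present"], ["PR", "PEA"])


class TestStudentsT:
    def test_identical_samples(self):
        res = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_example(self):
        res = students_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert abs(res.statistic) == pytest.approx(3.6742346, abs=1e-6)
        assert res.df == 4

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(11) + 0.5
        r1, r2 = students_t(a, b), students_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy(self, seed):
        r = np.random.default_rng(seed)
        a = r.standard_normal(r.integers(3, 20))
        b = r.standard_normal(r.integers(3, 20)) + r.uniform(-1, 1)
        res = students_t(a, b)
        ref = sstats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-8)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_zero_variance_unequal_means_flagged(self):
        res = students_t([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(res.statistic)
        assert res.warning is not None


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(25)
        y = 0.5 * x + r.standard_normal(25)
        res = pearson_r(x, y)
        ref = sstats.pearsonr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-8)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestChiSquare:
    def test_identical_proportions(self):
        res = chi_square_prop(10, 20, 10, 20)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_small_difference_not_significant(self):
        assert chi_square_prop(29, 31, 30, 31).p_value > 0.05

    def test_large_difference_significant(self):
        assert chi_square_prop(15, 31, 29, 31).p_value < 0.001

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy(self, seed):
        r = np.random.default_rng(seed)
        n1, n2 = int(r.integers(10, 60)), int(r.integers(10, 60))
        k1, k2 = int(r.integers(1, n1)), int(r.integers(1, n2))
        res = chi_square_prop(k1, n1, k2, n2)
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        chi2, p, dof, _ = sstats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(chi2, abs=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-8)


class TestCompareAuc:
    def test_identical_scores(self, rng):
        scores = rng.standard_normal(40)
        labels = np.array(["PR"] * 15 + ["PEA"] * 25)
        res = compare_auc(scores, scores, labels)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_power_on_separated_aucs(self):
        """A detector with AUC ~0.95 beats one with ~0.70 nearly always."""
        r = np.random.default_rng(1)
        rejections = 0
        n_trials = 60
        for _ in range(n_trials):
            labels = np.array(["PR"] * 80 + ["PEA"] * 80)
            truth = (labels == "PR").astype(float)
            a = truth * 2.4 + r.standard_normal(160)  # AUC ~0.95
            b = truth * 0.75 + r.standard_normal(160)  # AUC ~0.70
            if compare_auc(a, b, labels).p_value < 0.05:
                rejections += 1
        assert rejections / n_trials > 0.9

    def test_hanley_mode_agrees_in_sign(self, rng):
        labels = np.array(["PR"] * 30 + ["PEA"] * 40)
        truth = (labels == "PR").astype(float)
        a = truth * 2 + rng.standard_normal(70)
        b = truth * 1 + rng.standard_normal(70)
        z1 = compare_auc(a, b, labels, method="delong").statistic
        z2 = compare_auc(a, b, labels, method="hanley").statistic
        assert np.sign(z1) == np.sign(z2)


class TestEvaluateFeature:
    def _table(self, rng, delta=4.0):
        rows = []
        for split, n_pr, n_pea in [("training", 20, 40), ("testing", 20, 40)]:
            for i in range(n_pr + n_pea):
                is_pr = i < n_pr
                rows.append({
                    "segment_id": f"{split}{i}",
                    "set_assignment": split,
                    "label": "PR" if is_pr else "PEA",
                    "map_mmhg": 100 + rng.normal() if is_pr else 15 + rng.normal(),
                    "ccp": (delta if is_pr else 0.0) + rng.normal(),
                    "hr_bpm": 150 + 10 * rng.normal(),
                })
        return FeatureTable(pd.DataFrame(rows))

    def test_separated_gaussians_reach_high_auc(self, rng):
        rep = evaluate_feature(self._table(rng), "CCp", split="testing")
        assert rep.auc >= 0.99
        assert rep.accuracy >= 0.95

    def test_counts_partition_by_class(self, rng):
        rep = evaluate_feature(self._table(rng), "MAP", split="testing")
        assert rep.tp + rep.fn == 20
        assert rep.tn + rep.fp == 40
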