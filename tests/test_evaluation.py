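"""Confusion metrics, ROC/AUC, cross-validation splitting, Welch's test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifrpred.evaluation import (
    ConfusionCounts,
    UndefinedMetricError,
    accuracy,
    confusion,
    cutoff_screen,
    kfold_split,
    mcc,
    precision,
    precision_at_coverage,
    roc_auc,
    sensitivity,
    welch_compare,
)


class TestMcc:
    def test_perfect_classifier(self):
        assert mcc(ConfusionCounts(tp=50, tn=50, fp=0, fn=0)) == 1.0

    def test_random_assignment_near_zero(self, rng):
        y = rng.integers(0, 2, 100000)
        pred = rng.integers(0, 2, 100000)
        c = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (y == 1))),
            tn=int(np.sum((pred == 0) & (y == 0))),
            fp=int(np.sum((pred == 1) & (y == 0))),
            fn=int(np.sum((pred == 0) & (y == 1))))
        assert abs(mcc(c)) < 0.01

    def test_matches_brute_force_formula(self):
        c = ConfusionCounts(tp=10, tn=20, fp=5, fn=3)
        expected = (10 * 20 - 5 * 3) / math.sqrt(
            (10 + 5) * (10 + 3) * (20 + 5) * (20 + 3))
        assert mcc(c) == pytest.approx(expected, abs=1e-15)

    def test_zero_denominator_gives_zero(self):
        assert mcc(ConfusionCounts(tp=0, tn=10, fp=0, fn=5)) == 0.0

    @settings(deadline=None, max_examples=80)
    @given(st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50), st.integers(0, 50))
    def test_symmetric_under_class_and_prediction_swap(self, tp, tn, fp, fn):
        a = mcc(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        b = mcc(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
        assert a == pytest.approx(b, abs=1e-12)


class TestRatioMetrics:
    def test_all_correct(self):
        c = ConfusionCounts(tp=7, tn=3, fp=0, fn=0)
        assert accuracy(c) == 1.0
        assert precision(c) == 1.0
        assert sensitivity(c) == 1.0

    def test_degenerate_no_predicted_positives(self):
        c = ConfusionCounts(tp=0, tn=10, fp=0, fn=4)
        assert precision(c) is None          # undefined, not zero
        assert sensitivity(c) == 0.0

    def test_match_brute_force_ratios(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 40, 4)
            c = ConfusionCounts(tp=int(tp), tn=int(tn),
                                fp=int(fp), fn=int(fn))
            assert accuracy(c) == pytest.approx((tp + tn) / (tp + tn + fp + fn))
            assert precision(c) == pytest.approx(tp / (tp + fp))
            assert sensitivity(c) == pytest.approx(tp / (tp + fn))


def mann_whitney_auc(scores, labels):
    """Concordant-pair AUC with half credit for ties (exhaustive)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        rep = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert rep.auc == 1.0
        assert rep.max_mcc == 1.0

    def test_random_scores_near_half(self, rng):
        y = (rng.uniform(size=50000) < 0.3).astype(int)
        s = rng.uniform(size=50000)
        assert abs(roc_auc(s, y).auc - 0.5) < 0.01

    def test_trapezoid_equals_pair_counting_with_ties(self, rng):
        scores = rng.integers(0, 5, 20) / 4.0  # heavy ties
        labels = rng.integers(0, 2, 20)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        rep = roc_auc(scores, labels)
        assert rep.auc == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        metrics = pytest.importorskip("sklearn.metrics")
        s = rng.normal(size=500)
        y = (s + rng.normal(size=500) > 0).astype(int)
        assert roc_auc(s, y).auc == pytest.approx(
            metrics.roc_auc_score(y, s), abs=1e-12)

    def test_roc_points_monotone_in_fpr(self, rng):
        s = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        pts = roc_auc(s, y).roc_points
        fprs = [p[0] for p in pts]
        assert all(b >= a for a, b in zip(fprs, fprs[1:]))

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.9], [1, 1])


class TestKfold:
    def test_20_entries_give_folds_of_two(self):
        ids = [f"P{i:02d}" for i in range(20)]
        fa = kfold_split(ids, k=10, seed=4)
        sizes = [len(fa.test_ids(f)) for f in range(10)]
        assert sizes == [2] * 10

    def test_same_seed_identical_assignment(self):
        ids = [f"P{i:02d}" for i in range(25)]
        assert kfold_split(ids, 10, 7).folds == kfold_split(ids, 10, 7).folds

    def test_different_seed_differs(self):
        ids = [f"P{i:02d}" for i in range(25)]
        assert kfold_split(ids, 10, 1).folds != kfold_split(ids, 10, 2).folds

    def test_partition_properties(self):
        ids = [f"P{i:02d}" for i in range(23)]
        fa = kfold_split(ids, 10, 0)
        assert sorted(fa.folds) == sorted(ids)
        sizes = sorted(len(fa.test_ids(f)) for f in range(10))
        assert sizes[-1] - sizes[0] <= 1

    def test_residues_inherit_entry_fold(self):
        # entry-level split: every residue of an entry lands in its fold
        ids = [f"P{i}" for i in range(12)]
        fa = kfold_split(ids, 4, 3)
        residues = [(pdb, r) for pdb in ids for r in range(30)]
        for pdb, _ in residues:
            assert fa.fold_of(pdb) == fa.folds[pdb]

    def test_too_few_entries_raises(self):
        with pytest.raises(ValueError):
            kfold_split(["a", "b"], k=10)


class TestCutoffScreen:
    def test_extreme_cutoffs(self, rng):
        s = rng.uniform(size=500)
        y = rng.integers(0, 2, 500)
        rows = cutoff_screen(s, y, cutoffs=(0.0, 1.0 + 1e-9))
        assert rows[0]["sensitivity"] == 1.0       # everything called IFR
        assert rows[1]["tp"] + rows[1]["fp"] == 0  # nothing called IFR

    def test_sensitivity_monotone_nonincreasing(self, rng):
        s = np.concatenate([rng.normal(1.5, 1, 300), rng.normal(0, 1, 300)])
        s = 1 / (1 + np.exp(-s))
        y = np.r_[np.ones(300, dtype=int), np.zeros(300, dtype=int)]
        rows = cutoff_screen(s, y)
        sens = [r["sensitivity"] for r in rows]
        assert all(b <= a for a, b in zip(sens, sens[1:]))

    def test_precision_trend_on_separable_data(self, rng):
        s = np.concatenate([rng.normal(2.5, 1, 500), rng.normal(0, 1, 500)])
        s = 1 / (1 + np.exp(-s))
        y = np.r_[np.ones(500, dtype=int), np.zeros(500, dtype=int)]
        rows = cutoff_screen(s, y)
        precs = [r["precision"] for r in rows if r["precision"] is not None]
        # non-decreasing trend within noise: final >= first
        assert precs[-1] >= precs[0]


class TestWelch:
    def test_identical_samples(self):
        t, p = welch_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_gaussians_significant(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(3, 1, 10)
        _, p = welch_compare(a, b)
        assert p < 0.01

    def test_hand_computed_three_vs_three(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_expected = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 2 + vb ** 2 / 2)
        from scipy.stats import t as tdist
        p_expected = 2 * tdist.sf(abs(t_expected), df)
        t, p = welch_compare(a, b)
        assert t == pytest.approx(t_expected, abs=1e-12)
        assert p == pytest.approx(p_expected, abs=1e-12)


class TestPrecisionAtCoverage:
    def test_perfect_classifier_all_ones(self):
        s = [0.9, 0.8, 0.2, 0.1]
        y = [1, 1, 0, 0]
        rep = roc_auc(s, y)
        rows = precision_at_coverage(rep, s, y, [0.25, 0.5, 1.0])
        assert all(r["attained"] and r["precision"] == 1.0 for r in rows)

    def test_full_coverage_precision_is_base_rate(self, rng):
        y = (rng.uniform(size=5000) < 0.3).astype(int)
        s = rng.uniform(size=5000)
        rep = roc_auc(s, y)
        rows = precision_at_coverage(rep, s, y, [1.0])
        assert rows[0]["precision"] == pytest.approx(y.mean(), abs=0.02)

    def test_matches_brute_force_cutoff_scan(self, rng):
        s = rng.uniform(size=300)
        y = rng.integers(0, 2, 300)
        rep = roc_auc(s, y)
        level = 0.6
        row = precision_at_coverage(rep, s, y, [level])[0]
        # brute force: scan all distinct cutoffs for the smallest
        # sensitivity >= level
        best = None
        for cut in sorted(set(s)):
            c = confusion(s, y, cut)
            sens = sensitivity(c)
            if sens >= level and (best is None or sens < best[0]):
                best = (sens, precision(c))
        assert row["attained"]
        assert row["precision"] == pytest.approx(best[1])
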