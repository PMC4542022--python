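"""ROC/AUC, threshold selection, confusion-matrix metrics, repeated
stratified CV, t-test and Pearson-system family classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fuzzylvef import (
    CohortTable,
    LogisticClassifier,
    auc,
    metrics_at,
    pearson_system_family,
    repeated_stratified_cv,
    roc_curve,
    select_threshold,
    two_sample_ttest,
)
from oracles import auc_bruteforce


class TestAUC:
    def test_worked_example(self):
        """3 of the 4 positive-negative pairs are concordant -> 0.75,
        confirmed by the brute-force pairwise oracle."""
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert auc(scores, labels) == pytest.approx(0.75)
        assert auc_bruteforce(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10000)
        labels = rng.integers(0, 2, 10000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])

    @settings(deadline=None, max_examples=100)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_trapezoid_equals_mann_whitney(self, seed):
        """Trapezoidal area of the stored ROC equals the rank-based
        Mann-Whitney AUC to 1e-12, ties included."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 60)
        scores = np.round(rng.random(n), 2)  # rounding induces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(auc(scores, labels), abs=1e-12)

    def test_matches_sklearn_oracle(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = np.round(rng.random(50), 1)
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc(scores, labels) == pytest.approx(
                sk.roc_auc_score(labels, scores), abs=1e-12
            )


class TestROCInvariants:
    def test_monotone_sensitivity_specificity(self):
        rng = np.random.default_rng(1)
        roc = roc_curve(rng.random(200), rng.integers(0, 2, 200))
        assert (np.diff(roc.sensitivity) <= 1e-12).all()
        assert (np.diff(roc.specificity) >= -1e-12).all()
        assert roc.thresholds[-1] == np.inf


class TestSelectThreshold:
    def test_perfect_scores_reach_j_of_one(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        roc = roc_curve(scores, labels)
        t = select_threshold(roc)
        acc, sens, spec = metrics_at(scores, labels, t)
        assert sens + spec - 1 == pytest.approx(1.0)

    def test_symmetric_gaussians_threshold_near_midpoint(self):
        rng = np.random.default_rng(2)
        scores = np.r_[rng.normal(0.4, 0.1, 5000), rng.normal(0.6, 0.1, 5000)]
        labels = np.r_[np.zeros(5000, dtype=int), np.ones(5000, dtype=int)]
        t = select_threshold(roc_curve(scores, labels))
        assert t == pytest.approx(0.5, abs=0.05)

    def test_chosen_j_is_maximal(self):
        rng = np.random.default_rng(3)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        roc = roc_curve(scores, labels)
        t = select_threshold(roc)
        best_j = max(
            s + p - 1 for s, p in zip(roc.sensitivity, roc.specificity)
        )
        _, sens, spec = metrics_at(scores, labels, t)
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)

    def test_closest_corner_criterion_available(self):
        rng = np.random.default_rng(4)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        roc = roc_curve(scores, labels)
        assert np.isfinite(select_threshold(roc, criterion="closest"))


class TestMetricsAt:
    def test_all_correct(self):
        assert metrics_at([0.9, 0.8, 0.1], [1, 1, 0], 0.5) == (1.0, 1.0, 1.0)

    def test_degenerate_threshold_all_positive(self):
        acc, sens, spec = metrics_at([0.2, 0.7], [0, 1], -1.0)
        assert sens == 1.0 and spec == 0.0

    def test_accuracy_identity(self):
        rng = np.random.default_rng(5)
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        prev = labels.mean()
        acc, sens, spec = metrics_at(scores, labels, 0.4)
        assert acc == pytest.approx(prev * sens + (1 - prev) * spec)


class TestRepeatedStratifiedCV:
    @staticmethod
    def _builder(table, seed):
        return LogisticClassifier.from_cohort(table).fit()

    def test_fold_sizes_and_record_count(self, small_table):
        report = repeated_stratified_cv(self._builder, small_table, k=5, repetitions=3, seed=0)
        assert len(report.records) == 15
        assert set(report.records["repetition"]) == {0, 1, 2}

    def test_reproducible_under_fixed_seed(self, small_table):
        a = repeated_stratified_cv(self._builder, small_table, k=5, repetitions=2, seed=9)
        b = repeated_stratified_cv(self._builder, small_table, k=5, repetitions=2, seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_summary_recomputable_from_records(self, small_table):
        report = repeated_stratified_cv(self._builder, small_table, k=5, repetitions=2, seed=1)
        s = report.summary()
        assert s.loc["auc", "mean"] == pytest.approx(report.records["auc"].mean())
        assert s.loc["auc", "std"] == pytest.approx(report.records["auc"].std())

    def test_constant_builder_gives_tie_convention_auc(self, small_table):
        class Constant:
            threshold = 0.5

            def predict_score(self, exog):
                return np.full(len(exog), 0.5)

        report = repeated_stratified_cv(
            lambda t, s: Constant(), small_table, k=5, repetitions=1, seed=0
        )
        assert (report.records["auc"] == 0.5).all()

    def test_class_smaller_than_k_rejected(self):
        frame = pd.DataFrame({"x": np.arange(10.0)})
        table = CohortTable(frame, pd.Series([1, 1, 1] + [0] * 7, index=frame.index))
        with pytest.raises(ValueError):
            repeated_stratified_cv(self._builder, table, k=5, repetitions=1, seed=0)

    def test_fold_partition_arithmetic(self):
        from fuzzylvef.evaluation import _stratified_fold_ids

        y = np.r_[np.ones(23, dtype=int), np.zeros(77, dtype=int)]
        ids = _stratified_fold_ids(y, 5, np.random.default_rng(0))
        sizes = np.bincount(ids)
        assert sizes.max() - sizes.min() <= 2  # <=1 per class, 2 classes


class TestTwoSampleTTest:
    def test_identical_samples(self):
        t, p = two_sample_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_large_effect(self):
        rng = np.random.default_rng(6)
        t, p = two_sample_ttest(rng.normal(0, 1, 100), rng.normal(5, 1, 100))
        assert p < 1e-10

    def test_welch_matches_closed_form(self):
        """Welch statistic and p-value re-derived from first principles."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(5, 40))
            b = rng.normal(0.3, 2, rng.integers(5, 40))
            t, p = two_sample_ttest(a, b, welch=True)
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
            p_ref = 2 * stats.t.sf(abs(t_ref), df)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_pooled_variant(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        t, p = two_sample_ttest(a, b, welch=False)
        assert (t, p) == pytest.approx((t_ref, p_ref))


class TestPearsonSystem:
    def test_normal_sample(self):
        x = np.random.default_rng(9).standard_normal(100_000)
        assert pearson_system_family(x) == "normal"

    def test_exponential_sample_is_skewed_family(self):
        x = np.random.default_rng(10).exponential(1.0, 100_000)
        label = pearson_system_family(x)
        assert label not in ("normal", "II (symmetric beta)", "VII (Student t)")

    def test_affine_invariance(self):
        rng = np.random.default_rng(11)
        x = rng.gamma(3.0, size=50_000)
        base = pearson_system_family(x)
        assert pearson_system_family(5.0 * x - 2.0) == base
        assert pearson_system_family(-0.5 * x + 7.0) == base

    def test_heavy_tailed_symmetric_is_type_vii(self):
        x = np.random.default_rng(12).standard_t(df=6, size=200_000)
        assert pearson_system_family(x) == "VII (Student t)"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_system_family(np.ones(100))

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            pearson_system_family([1.0, 2.0, 3.0])
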