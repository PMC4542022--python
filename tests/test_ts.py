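"""Takagi-Sugeno model: printed-rule fixture, identification, inference."""

import warnings

import numpy as np
import pandas as pd
import pytest

from fuzzylvef import (
    CohortTable,
    GaussianMF,
    TakagiSugenoClassifier,
    TSModel,
    TSRule,
    classify,
    gk_cluster,
    identify_ts_model,
    load_printed_rules,
    project_memberships,
    repeated_stratified_cv,
    ts_evaluate,
)

ZERO7 = np.zeros(7)


class TestPrintedRules:
    """The published two-rule, seven-input fitted model, transcribed exactly."""

    def test_rule_offsets_at_zero_input(self):
        model = load_printed_rules()
        assert float(model.rules[0].consequent(ZERO7)[0]) == 0.5000
        assert float(model.rules[1].consequent(ZERO7)[0]) == 0.1400

    def test_every_coefficient(self):
        model = load_printed_rules()
        np.testing.assert_array_equal(
            model.rules[0].consequent_a,
            [-0.0093, 0.0670, 0.2700, 0.5000, -1.200, 0.4000, 0.0540],
        )
        np.testing.assert_array_equal(
            model.rules[1].consequent_a,
            [-0.4300, 0.3100, 0.5000, 0.2400, -0.0280, -0.1500, -0.3600],
        )

    def test_sodium_coefficient_rule1(self):
        model = load_printed_rules()
        idx = model.input_names.index("sodium")
        assert model.rules[0].consequent_a[idx] == -1.200

    def test_equal_activation_output_is_mean_of_offsets(self):
        """Constant antecedents activate both rules equally, so the
        weighted-sum output at the all-zeros input is the mean of the two
        printed offsets: (0.5000 + 0.1400) / 2 = 0.3200."""
        model = load_printed_rules()
        assert ts_evaluate(model, ZERO7) == pytest.approx(0.3200, abs=1e-12)

    def test_input_naming(self):
        model = load_printed_rules()
        assert model.input_names[0] == "systolic_nbp"
        assert len(model.input_names) == 7


class TestInference:
    def _two_rule_model(self, threshold=None):
        rules = (
            TSRule(
                antecedents=(GaussianMF(0.2, 0.1),),
                consequent_a=np.array([1.0]),
                consequent_b=0.0,
            ),
            TSRule(
                antecedents=(GaussianMF(0.8, 0.1),),
                consequent_a=np.array([-1.0]),
                consequent_b=1.0,
            ),
        )
        return TSModel(rules=rules, input_names=("x1",), threshold=threshold)

    def test_single_active_rule_returns_its_affine_value(self):
        model = self._two_rule_model()
        # at x = 0.2 rule 1 activation is 1, rule 2 activation ~ e^-18
        assert ts_evaluate(model, np.array([0.2])) == pytest.approx(0.2, abs=1e-6)

    def test_output_is_convex_combination_of_rule_outputs(self):
        model = self._two_rule_model()
        rng = np.random.default_rng(0)
        X = rng.random((200, 1))
        out = model.evaluate(X)
        y_rules = np.stack([r.consequent(X) for r in model.rules])
        assert (out >= y_rules.min(axis=0) - 1e-12).all()
        assert (out <= y_rules.max(axis=0) + 1e-12).all()

    def test_activation_rescaling_invariance(self):
        """Scaling every rule activation by a common factor cancels in the
        weighted sum (normalization identity)."""
        model = self._two_rule_model()
        x = np.array([[0.5]])
        beta = np.stack([r.activation(x) for r in model.rules])
        y_rules = np.stack([r.consequent(x) for r in model.rules])
        direct = model.evaluate(x)[0]
        for factor in (0.1, 3.0, 1e6):
            scaled = (factor * beta * y_rules).sum() / (factor * beta).sum()
            assert scaled == pytest.approx(direct, rel=1e-12)

    def test_all_rules_inactive_fallback_is_rule_mean(self):
        rules = (
            TSRule((GaussianMF(0.0, 1e-3),), np.array([0.0]), 2.0),
            TSRule((GaussianMF(0.0, 1e-3),), np.array([0.0]), 4.0),
        )
        model = TSModel(rules=rules, input_names=("x1",))
        assert ts_evaluate(model, np.array([0.9])) == pytest.approx(3.0)

    def test_classify_threshold_convention(self):
        model = self._two_rule_model(threshold=0.5)
        # score at x=0.2 is ~0.2 -> class 0; >= threshold maps to class 1
        assert classify(model, np.array([0.2])) == 0
        rules_const = (TSRule((GaussianMF(),), np.array([0.0]), 0.5),)
        m2 = TSModel(rules=rules_const, input_names=("x1",), threshold=0.5)
        assert classify(m2, np.array([0.3])) == 1  # output exactly at threshold

    def test_uncalibrated_classify_is_state_error(self):
        model = self._two_rule_model(threshold=None)
        with pytest.raises(RuntimeError):
            classify(model, np.array([0.2]))

    def test_dimension_mismatch(self):
        model = self._two_rule_model()
        with pytest.raises(ValueError):
            model.evaluate(np.zeros((1, 3)))

    def test_lower_threshold_never_decreases_sensitivity(self):
        rng = np.random.default_rng(1)
        scores = rng.random(300)
        labels = (rng.random(300) < scores).astype(int)
        from fuzzylvef import metrics_at

        sens = [
            metrics_at(scores, labels, t)[1] for t in np.linspace(1.0, 0.0, 21)
        ]
        assert (np.diff(sens) >= 0).all()


class TestIdentification:
    def test_single_rule_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(2)
        X = rng.random((100, 3))
        y = X @ [1.0, -2.0, 0.5] + 0.3
        model = identify_ts_model(X, y, c=1, seed=0)
        coef, b = model.rules[0].consequent_a, model.rules[0].consequent_b
        np.testing.assert_allclose(coef, [1.0, -2.0, 0.5], atol=1e-6)
        assert b == pytest.approx(0.3, abs=1e-6)
        assert np.sqrt(np.mean((model.evaluate(X) - y) ** 2)) < 1e-6

    def test_piecewise_linear_slope_recovery(self):
        """Two linear regimes separated by a gap: per-rule slopes recovered
        within 5%."""
        rng = np.random.default_rng(0)
        x = np.r_[rng.uniform(0, 0.4, 200), rng.uniform(0.6, 1.0, 200)][:, None]
        y = np.where(x[:, 0] < 0.5, 0.2 + 0.5 * x[:, 0], -0.8 + 2.0 * x[:, 0])
        model = identify_ts_model(x, y, c=2, seed=1)
        slopes = sorted(float(r.consequent_a[0]) for r in model.rules)
        assert slopes[0] == pytest.approx(0.5, rel=0.05)
        assert slopes[1] == pytest.approx(2.0, rel=0.05)

    def test_self_consistency_cv_auc(self):
        """Labels produced by thresholding a known TS model are recovered
        with CV AUC >= 0.95 by a freshly identified model."""
        rng = np.random.default_rng(5)
        X = rng.random((600, 3))
        source = identify_ts_model(
            X, (X @ [1.0, -1.0, 0.5] > 0.25).astype(float), c=2, seed=0
        )
        scores = source.evaluate(X)
        labels = (scores >= np.median(scores)).astype(int)
        table = CohortTable(
            pd.DataFrame(X, columns=["a", "b", "c"]), pd.Series(labels)
        )

        def builder(t, seed):
            return TakagiSugenoClassifier.from_cohort(t, normalize=False).fit(seed=seed)

        report = repeated_stratified_cv(builder, table, k=5, repetitions=2, seed=0)
        assert report.records["auc"].mean() >= 0.95

    def test_unnormalized_inputs_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(50, 10, size=(50, 2))
        with pytest.raises(ValueError):
            identify_ts_model(X, rng.integers(0, 2, 50), c=1)

    def test_sample_size_precondition(self):
        X = np.random.default_rng(0).random((5, 3))
        with pytest.raises(ValueError):
            identify_ts_model(X, np.r_[1.0, 0, 1, 0, 1], c=2)


class TestProjection:
    def test_peak_at_projected_center(self):
        rng = np.random.default_rng(4)
        X = np.c_[
            np.r_[rng.normal(0.3, 0.03, 100), rng.normal(0.7, 0.03, 100)],
            rng.random(200),
        ]
        part, _ = gk_cluster(X, c=2, seed=0)
        mfs = project_memberships(part, X, 0)
        mus = sorted(mf.mu for mf in mfs)
        assert mus[0] == pytest.approx(0.3, abs=0.05)
        assert mus[1] == pytest.approx(0.7, abs=0.05)
        # peaks ordered like the cluster centers; codomain [0, 1]
        grid = np.linspace(-1, 2, 301)
        for mf in mfs:
            vals = mf.evaluate(grid)
            assert (vals >= 0).all() and (vals <= 1).all()
            assert mf.evaluate(np.array([mf.mu]))[0] == pytest.approx(1.0)

    def test_degenerate_axis_flat_with_warning(self):
        X = np.c_[np.r_[np.zeros(20), np.ones(20)], np.random.default_rng(1).random(40)]
        part, _ = gk_cluster(X, c=2, seed=0)
        with pytest.warns(RuntimeWarning):
            mfs = project_memberships(part, X, 0)
        np.testing.assert_allclose(mfs[0].evaluate(np.linspace(-5, 5, 11)), 1.0)


class TestSerialization:
    def test_json_round_trip_outputs_identical(self):
        rng = np.random.default_rng(6)
        X = rng.random((200, 4))
        y = (X @ [1.0, -0.5, 0.2, 0.8] > 0.7).astype(int)
        model = identify_ts_model(X, y, c=2, seed=1)
        model.threshold = 0.4
        clone = TSModel.from_json(model.to_json())
        probe = rng.random((1000, 4))
        np.testing.assert_allclose(
            clone.evaluate(probe), model.evaluate(probe), rtol=0, atol=1e-12
        )
        assert clone.input_names == model.input_names
        assert clone.threshold == model.threshold

    def test_printed_rules_survive_round_trip_exactly(self):
        model = load_printed_rules()
        clone = TSModel.from_json(model.to_json())
        for r1, r2 in zip(model.rules, clone.rules):
            np.testing.assert_array_equal(r1.consequent_a, r2.consequent_a)
            assert r1.consequent_b == r2.consequent_b


class TestModelResultsSurface:
    def test_fit_predict_summary(self, small_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = TakagiSugenoClassifier.from_cohort(small_table).fit(seed=0)
        preds = res.predict()
        assert set(np.unique(preds)) <= {0, 1}
        metrics = res.training_metrics()
        assert metrics["auc"] > 0.9  # clean planted signal
        text = res.summary()
        assert "Takagi-Sugeno" in text and "signal" in text
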