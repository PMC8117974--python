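import numpy as np
import pytest
from scipy import stats

from nuva.calibration import (LabeledDistances, ThresholdCalibration,
                              calibrate, cross_validate, threshold_sweep)

from ._oracles import confusion_table_metric


def make_data(distances, truth, patients=None):
    n = len(distances)
    patients = patients or ["P1"] * n
    records = [(patients[i], f"i{i}", distances[i], truth[i]) for i in range(n)]
    return LabeledDistances.from_records(records)


class TestLabeledDistances:
    def test_rejects_negative_distances(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_data([0.5, -0.1], [1, 0])

    def test_rejects_duplicate_keys(self):
        records = [("P1", "i0", 0.5, 1), ("P1", "i0", 0.6, 0)]
        with pytest.raises(ValueError, match="duplicate"):
            LabeledDistances.from_records(records)

    def test_accepts_string_truth_labels(self):
        data = make_data([0.2, 0.8], ["correct", "incorrect"])
        np.testing.assert_array_equal(data.truth, [1, 0])


class TestThresholdSweep:
    def test_perfect_separation_reaches_r_one_in_the_gap(self):
        data = make_data([0.2, 0.3, 0.8, 0.9], [1, 1, 0, 0])
        threshold, best = threshold_sweep(data).best()
        assert best == pytest.approx(1.0)
        assert 0.3 < threshold < 0.8

    def test_matches_confusion_table_oracle_on_toy_set(self):
        d = [0.1, 0.25, 0.4, 0.5, 0.7, 0.95]
        y = [1, 1, 0, 1, 0, 0]
        curve = threshold_sweep(make_data(d, y))
        for t, v in zip(curve.thresholds, curve.metric_values):
            expected = confusion_table_metric(d, y, t, "pearson_r")
            if np.isnan(expected):
                assert np.isnan(v)
            else:
                assert v == pytest.approx(expected, abs=1e-12)

    def test_shuffled_labels_give_metric_near_zero(self, rng):
        n = 1000
        d = rng.uniform(0, 1, n)
        y = rng.permutation(np.repeat([0, 1], n // 2))
        _, best = threshold_sweep(make_data(d, y)).best()
        assert best < 0.12  # max over ~n thresholds of a null statistic

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both truth classes"):
            threshold_sweep(make_data([0.1, 0.2], [1, 1]))

    def test_best_metric_invariant_under_monotone_transform(self, rng):
        d = rng.uniform(0.1, 1.0, 60)
        y = (d + rng.normal(0, 0.2, 60) < 0.5).astype(int)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        base = threshold_sweep(make_data(d, y)).best()[1]
        transformed = threshold_sweep(make_data(np.exp(2 * d) - 1, y)).best()[1]
        assert transformed == pytest.approx(base, abs=1e-12)


class TestCalibrate:
    def test_single_patient_fixed_equals_adapted(self, rng):
        d = rng.uniform(0, 1, 40)
        y = (d < 0.45).astype(int)
        data = make_data(d, y)
        fixed = calibrate(data, "fixed")
        adapted = calibrate(data, "adapted")
        assert adapted.threshold_for("P1") == pytest.approx(
            fixed.threshold_for())

    def test_disjoint_patients_favour_adapted(self):
        # P1 separates at ~0.5, P2 at ~1.5; no single threshold does both
        d = [0.2, 0.3, 0.8, 0.9, 1.2, 1.3, 1.8, 1.9]
        y = [1, 1, 0, 0, 1, 1, 0, 0]
        p = ["P1"] * 4 + ["P2"] * 4
        data = make_data(d, y, p)
        adapted = calibrate(data, "adapted")
        assert adapted.best_metric["P1"] == pytest.approx(1.0)
        assert adapted.best_metric["P2"] == pytest.approx(1.0)
        fixed = calibrate(data, "fixed")
        assert fixed.best_metric < 1.0

    def test_fixed_metric_never_beats_mean_adapted_metric(self, rng):
        d = rng.uniform(0, 2, 120)
        y = rng.integers(0, 2, 120)
        p = [f"P{i % 3}" for i in range(120)]
        data = make_data(d, y, p)
        fixed = calibrate(data, "fixed")
        adapted = calibrate(data, "adapted")
        assert fixed.best_metric <= np.mean(list(adapted.best_metric.values())) + 1e-12

    def test_unknown_mode_rejected(self, rng):
        data = make_data([0.1, 0.9], [1, 0])
        with pytest.raises(ValueError, match="mode"):
            ThresholdCalibration(data, mode="bayes")

    def test_adapted_single_class_patient_named_in_error(self):
        d = [0.1, 0.9, 0.2, 0.3]
        y = [1, 0, 1, 1]
        p = ["P1", "P1", "P2", "P2"]
        with pytest.raises(ValueError, match="P2"):
            calibrate(make_data(d, y, p), "adapted")

    def test_summary_mentions_mode_and_threshold(self, rng):
        data = make_data([0.2, 0.3, 0.8, 0.9], [1, 1, 0, 0])
        text = calibrate(data, "fixed").summary()
        assert "fixed" in text and "threshold" in text


class TestCrossValidate:
    def test_separable_study_size_data_is_perfect(self, rng):
        n = 220
        y = rng.integers(0, 2, n)
        d = np.where(y == 1, rng.uniform(0.1, 0.4, n), rng.uniform(0.6, 0.9, n))
        cv = cross_validate(make_data(d, y), k=10, seed=3)
        assert cv.aggregate.loc["accuracy", "mean"] == pytest.approx(1.0)

    def test_same_seed_reproduces_folds_and_results(self, rng):
        d = rng.uniform(0, 1, 100)
        y = rng.integers(0, 2, 100)
        data = make_data(d, y)
        a = cross_validate(data, k=5, seed=11)
        b = cross_validate(data, k=5, seed=11)
        assert a.folds.equals(b.folds)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(make_data([0.1, 0.9], [1, 0]), k=10)

    def test_overlapping_classes_recover_bayes_accuracy(self, rng):
        # correct ~ N(0.4, 0.1), incorrect ~ N(0.8, 0.1), equal priors:
        # optimal threshold 0.6, Bayes accuracy = Phi(2) ~= 0.9772
        n = 400
        y = rng.permutation(np.repeat([0, 1], n // 2))
        d = np.where(y == 1, rng.normal(0.4, 0.1, n), rng.normal(0.8, 0.1, n))
        d = np.abs(d)
        cv = cross_validate(make_data(d, y), k=10, seed=5)
        bayes = stats.norm.cdf(2.0)
        mean = cv.aggregate.loc["accuracy", "mean"]
        sd = cv.aggregate.loc["accuracy", "sd"]
        assert abs(mean - bayes) <= 3 * max(sd, 1e-3)

    def test_cv_accuracy_not_above_within_sample_accuracy(self, rng):
        # in expectation the held-out accuracy cannot beat the in-sample
        # optimum; allow a small sampling margin
        n = 300
        y = rng.permutation(np.repeat([0, 1], n // 2))
        d = np.where(y == 1, rng.normal(0.4, 0.15, n), rng.normal(0.8, 0.15, n))
        d = np.abs(d)
        data = make_data(d, y)
        t, _ = threshold_sweep(data, "accuracy").best()
        within = np.mean((d < t).astype(int) == y)
        cv = cross_validate(data, k=10, seed=2, metric="accuracy")
        assert cv.aggregate.loc["accuracy", "mean"] <= within + 0.02
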