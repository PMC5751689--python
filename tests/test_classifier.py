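import numpy as np
import pytest

import nirsnet as nn
from nirsnet.classifier import ConfusionMatrix
from nirsnet.features import FeatureMatrix
from nirsnet.synthetic import planted_feature_tensor


def separable_toy():
    X = np.array([[5.0], [6.0], [-5.0], [-6.0]])
    y = np.array([1, 1, -1, -1])
    return X, y


def feature_matrix(values, labels):
    return FeatureMatrix(
        values=values, labels=labels, metric="degree", sparsity=0.21
    )


class TestTrainPredict:
    def test_separable_toy_training_accuracy(self):
        X, y = separable_toy()
        model = nn.train_svm(X, y)
        np.testing.assert_array_equal(nn.predict(model, X), y)

    def test_training_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        y = np.where(rng.random(30) < 0.5, 1, -1)
        y[:2] = [1, -1]
        m1 = nn.train_svm(X, y)
        m2 = nn.train_svm(X, y)
        probe = rng.standard_normal((10, 5))
        np.testing.assert_array_equal(
            nn.classifier.decision_values(m1, probe),
            nn.classifier.decision_values(m2, probe),
        )

    def test_paper_scale_shape_trains_and_predicts(self, rng):
        """75 training subjects x 52 features, one held-out row."""
        X = rng.standard_normal((76, 52))
        y = np.r_[np.full(42, 1), np.full(34, -1)]
        model = nn.train_svm(X[:75], y[:75])
        pred = nn.predict(model, X[75:])
        assert pred.shape == (1,) and pred[0] in (1, -1)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            nn.train_svm(np.zeros((3, 2)), np.array([1, 1, 1]))

    def test_empty_test_set_gives_empty_predictions(self):
        X, y = separable_toy()
        model = nn.train_svm(X, y)
        assert nn.predict(model, np.empty((0, 1))).size == 0

    def test_dimension_mismatch_rejected(self):
        X, y = separable_toy()
        model = nn.train_svm(X, y)
        with pytest.raises(ValueError, match="dimension"):
            nn.predict(model, np.zeros((2, 3)))

    def test_prediction_invariant_to_row_order(self, rng):
        X = rng.standard_normal((40, 6))
        y = np.where(X[:, 0] > 0, 1, -1)
        model = nn.train_svm(X, y)
        probe = rng.standard_normal((15, 6))
        perm = rng.permutation(15)
        np.testing.assert_array_equal(
            nn.predict(model, probe)[perm], nn.predict(model, probe[perm])
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            nn.SVMParams(C=-1.0)
        with pytest.raises(ValueError):
            nn.SVMParams(gamma=0.0)

    def test_gamma_auto_is_reciprocal_feature_count(self):
        X, y = separable_toy()
        model = nn.train_svm(X, y)
        assert model.svc.gamma == pytest.approx(1.0)  # 1 feature -> gamma 1


class TestLOOCV:
    def test_76_subjects_produce_76_folds(self, rng):
        fm = feature_matrix(
            rng.standard_normal((76, 52)), np.r_[np.full(42, 1), np.full(34, -1)]
        )
        report = nn.loocv(fm)
        assert len(report.folds) == 76
        assert {f.subject_id for f in report.folds} == {
            f"s{i + 1:03d}" for i in range(76)
        }

    def test_confusion_marginals_match_cohort_composition(self, rng):
        fm = feature_matrix(
            rng.standard_normal((30, 8)), np.r_[np.full(17, 1), np.full(13, -1)]
        )
        report = nn.loocv(fm)
        assert report.confusion.n_positive == 17
        assert report.confusion.n_negative == 13

    def test_perfectly_separated_cohort_classifies_all(self):
        """A 3-SD planted shift makes LOOCV accuracy 100%."""
        tensor, _ = planted_feature_tensor(
            effect_size=3.0, rng=np.random.default_rng(11)
        )
        fm = nn.select_feature_vector(tensor, "degree", 0.21)
        report = nn.loocv(fm)
        assert report.accuracy == 1.0

    def test_shuffled_labels_near_chance(self):
        """Null 20+20 cohort (shuffled labels): ACC inside the binomial
        chance band [35%, 65%]."""
        tensor, _ = planted_feature_tensor(
            effect_size=2.0, rng=np.random.default_rng(11)
        )
        rng = np.random.default_rng(3)
        labels = rng.permutation(tensor.labels)
        fm = feature_matrix(
            nn.select_feature_vector(tensor, "degree", 0.21).values, labels
        )
        report = nn.loocv(fm)
        assert 0.35 <= report.accuracy <= 0.65

    def test_result_invariant_to_subject_order(self, rng):
        tensor, _ = planted_feature_tensor(
            n_patients=12, n_controls=12, effect_size=1.0,
            rng=np.random.default_rng(9),
        )
        fm = nn.select_feature_vector(tensor, "degree", 0.21)
        perm = rng.permutation(24)
        fm_perm = FeatureMatrix(
            values=fm.values[perm], labels=fm.labels[perm],
            metric="degree", sparsity=0.21,
            subject_ids=[fm.subject_ids[i] for i in perm],
        )
        a, b = nn.loocv(fm), nn.loocv(fm_perm)
        assert a.confusion == b.confusion
        assert {(f.subject_id, f.predicted_label) for f in a.folds} == {
            (f.subject_id, f.predicted_label) for f in b.folds
        }

    def test_fold_mode_reselects_inside_each_fold(self):
        tensor, _ = planted_feature_tensor(
            n_patients=10, n_controls=10, effect_size=3.0,
            sparsities=np.array([0.1, 0.21, 0.3]),
            rng=np.random.default_rng(13),
        )
        report = nn.loocv(tensor=tensor, selection_mode="fold")
        assert len(report.folds) == 20
        # the strong planted signal is found in every fold
        assert all(f.chosen_metric == "degree" for f in report.folds)
        assert all(f.chosen_sparsity == pytest.approx(0.21) for f in report.folds)

    def test_single_class_cohort_rejected(self, rng):
        fm = feature_matrix(rng.standard_normal((6, 3)), np.full(6, 1))
        with pytest.raises(ValueError, match="both classes"):
            nn.loocv(fm)


class TestPerformanceMetrics:
    def test_oxy_table_values(self):
        """Confusion 39/3/8/26: ACC 85.5%, SS 92.9% (39/42), TNR 76.5%."""
        report = nn.performance_metrics(ConfusionMatrix(tp=39, fn=3, fp=8, tn=26))
        assert report.accuracy_pct == pytest.approx(85.5)
        assert report.sensitivity_pct == pytest.approx(92.9)
        assert report.specificity_pct == pytest.approx(76.5)
        assert report.accuracy == pytest.approx(65 / 76)

    def test_total_signal_table_values(self):
        """Confusion 39/3/12/22: ACC 80.3%, TNR 64.7%."""
        report = nn.performance_metrics(ConfusionMatrix(tp=39, fn=3, fp=12, tn=22))
        assert report.accuracy_pct == pytest.approx(80.3)
        assert report.specificity_pct == pytest.approx(64.7)
        assert report.sensitivity_pct == pytest.approx(92.9)

    def test_perfect_classifier(self):
        report = nn.performance_metrics(ConfusionMatrix(tp=42, fn=0, fp=0, tn=34))
        assert (report.accuracy, report.sensitivity, report.specificity) == (1, 1, 1)

    def test_zero_denominator_identifies_metric(self):
        with pytest.raises(ValueError, match="sensitivity"):
            nn.performance_metrics(ConfusionMatrix(tp=0, fn=0, fp=1, tn=1))
        with pytest.raises(ValueError, match="specificity"):
            nn.performance_metrics(ConfusionMatrix(tp=1, fn=1, fp=0, tn=0))

    def test_accuracy_is_class_weighted_combination(self, rng):
        """ACC = (P*SS + N*TNR)/(P+N) on arbitrary confusion counts."""
        for _ in range(20):
            tp, fn, fp, tn = (int(x) for x in rng.integers(1, 40, 4))
            r = nn.performance_metrics(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn))
            p, n = tp + fn, tn + fp
            assert r.accuracy == pytest.approx(
                (p * r.sensitivity + n * r.specificity) / (p + n)
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fn=0, fp=0, tn=1)
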