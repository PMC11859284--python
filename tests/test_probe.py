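"""Softmax probe: probabilities, NLL gradients, CV protocol, metrics."""

import numpy as np
import pytest

from clumm.encoder import EncoderConfig, build_encoder
from clumm.landmarks import build_feature_matrix
from clumm.probe import (
    ClassificationMetrics,
    ProbeConfig,
    ProbeWeights,
    _metrics_from_predictions,
    baseline_transfer,
    cross_validate,
    evaluate,
    nll_gradients,
    nll_loss,
    softmax_probabilities,
    train_probe,
)


def make_head(rng, k=3, d=6):
    return ProbeWeights(W=rng.normal(size=(k, d)), biases=rng.normal(size=k), classes=np.arange(k))


class TestSoftmax:
    def test_equal_scores_give_uniform(self):
        p = softmax_probabilities(np.zeros((1, 4)))
        np.testing.assert_allclose(p, 0.25)

    def test_two_class_closed_form(self):
        p = softmax_probabilities(np.array([[np.log(3.0), 0.0]]))
        np.testing.assert_allclose(p, [[0.75, 0.25]], atol=1e-12)

    def test_sums_to_one_within_1e12(self, rng):
        scores = rng.normal(scale=50, size=(100, 5))
        p = softmax_probabilities(scores)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all()

    def test_matches_naive_evaluation(self, rng):
        scores = rng.normal(size=(20, 4))
        naive = np.exp(scores) / np.exp(scores).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(softmax_probabilities(scores), naive, atol=1e-12)

    def test_shift_invariance(self, rng):
        scores = rng.normal(size=(5, 3))
        np.testing.assert_allclose(
            softmax_probabilities(scores), softmax_probabilities(scores + 123.0), atol=1e-12
        )

    def test_extreme_scores_stay_finite(self):
        p = softmax_probabilities(np.array([[1000.0, -1000.0, 0.0]]))
        assert np.isfinite(p).all() and p[0, 0] == pytest.approx(1.0)


class TestNLL:
    def test_perfect_predictions_give_zero(self):
        head = ProbeWeights(
            W=np.eye(3) * 1e4, biases=np.zeros(3), classes=np.arange(3)
        )
        X = np.eye(3)
        assert nll_loss(X, np.arange(3), head) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_probabilities_give_log_k(self, rng):
        head = ProbeWeights(W=np.zeros((4, 6)), biases=np.zeros(4), classes=np.arange(4))
        X = rng.normal(size=(10, 6))
        y = rng.integers(0, 4, size=10)
        assert nll_loss(X, y, head) == pytest.approx(np.log(4))

    def test_gradients_match_finite_differences(self, rng):
        """Numerical gradient of the mean NLL w.r.t. W and b on a 5-sample batch."""
        head = make_head(rng)
        X = rng.normal(size=(5, 6))
        y = rng.integers(0, 3, size=5)
        gw, gb = nll_gradients(X, y, head)
        eps = 1e-6
        for arr, grad in ((head.W, gw), (head.biases, gb)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                old = arr[idx]
                arr[idx] = old + eps
                up = nll_loss(X, y, head)
                arr[idx] = old - eps
                down = nll_loss(X, y, head)
                arr[idx] = old
                assert grad[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-5)


class TestTrainProbe:
    def make_separable_matrix(self, rng, n_per=30):
        centers = np.vstack([np.eye(3) * 4, np.zeros((0, 3))])
        rows, labels = [], []
        for k, name in enumerate(["a", "b", "c"]):
            pts = centers[k] + 0.05 * rng.normal(size=(n_per, 3))
            rows.append(np.hstack([pts, np.zeros((n_per, 27))]))
            labels += [name] * n_per
        return build_feature_matrix(np.vstack(rows), labels=labels)

    def test_separable_data_reaches_high_training_accuracy(self, rng):
        matrix = self.make_separable_matrix(rng)
        enc = build_encoder(EncoderConfig(kind="mlp"), rng)
        head, history = train_probe(enc, matrix, ProbeConfig(seed=0))
        metrics = evaluate(head, enc, matrix)
        assert metrics.accuracy >= 0.99
        assert history[-1] < history[0]

    def test_zero_epochs_leave_weights_at_init(self, rng, small_dataset):
        enc = build_encoder(EncoderConfig(kind="mlp"), rng)
        head, _ = train_probe(enc, small_dataset, ProbeConfig(epochs=0))
        assert (head.W == 0).all() and (head.biases == 0).all()

    def test_encoder_is_frozen(self, rng, small_dataset):
        enc = build_encoder(EncoderConfig(kind="mlp"), rng)
        before = [p.data.copy() for p in enc.parameters()]
        train_probe(enc, small_dataset, ProbeConfig(epochs=5))
        for old, p in zip(before, enc.parameters()):
            np.testing.assert_array_equal(old, p.data)

    def test_single_class_rejected(self, rng):
        matrix = build_feature_matrix(rng.normal(size=(10, 30)), labels=["x"] * 10)
        enc = build_encoder(EncoderConfig(kind="mlp"), rng)
        with pytest.raises(ValueError, match="two classes"):
            train_probe(enc, matrix)

    def test_unlabeled_matrix_rejected(self, rng):
        matrix = build_feature_matrix(rng.normal(size=(10, 30)))
        enc = build_encoder(EncoderConfig(kind="mlp"), rng)
        with pytest.raises(ValueError, match="labeled"):
            train_probe(enc, matrix)


class TestCrossValidate:
    def test_folds_partition_the_data(self, rng, small_dataset):
        enc = build_encoder(EncoderConfig(kind="mlp"), rng)
        folds, mean = cross_validate(enc, small_dataset, ProbeConfig(epochs=5, folds=5))
        supports = [f.confusion.sum() for f in folds]
        assert sum(supports) == len(small_dataset)
        assert max(supports) - min(supports) <= len(np.unique(small_dataset.labels))
        assert mean.confusion.sum() == len(small_dataset)

    def test_perfect_features_give_perfect_metrics(self, rng):
        matrix = TestTrainProbe().make_separable_matrix(rng, n_per=20)
        enc = build_encoder(EncoderConfig(kind="mlp"), rng)
        _, mean = cross_validate(enc, matrix, ProbeConfig(seed=0))
        assert mean.accuracy == mean.precision == mean.recall == mean.f1 == 1.0

    def test_duplicated_halves_give_near_identical_folds(self, rng):
        base = TestTrainProbe().make_separable_matrix(rng, n_per=20)
        doubled = build_feature_matrix(
            np.vstack([base.values, base.values]),
            labels=np.concatenate([base.labels, base.labels]),
        )
        enc = build_encoder(EncoderConfig(kind="mlp"), rng)
        folds, _ = cross_validate(enc, doubled, ProbeConfig(folds=2, seed=1))
        assert abs(folds[0].accuracy - folds[1].accuracy) <= 0.05

    def test_insufficient_class_count_names_offender(self, rng):
        matrix = build_feature_matrix(
            rng.normal(size=(13, 30)), labels=["a"] * 10 + ["rare"] * 3
        )
        enc = build_encoder(EncoderConfig(kind="mlp"), rng)
        with pytest.raises(ValueError, match="rare"):
            cross_validate(enc, matrix, ProbeConfig(folds=5))


class TestEvaluate:
    def test_all_correct_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        m = _metrics_from_predictions(y, y.copy(), np.array(["i", "l", "b"]))
        assert m.accuracy == m.precision == m.recall == m.f1 == 1.0
        np.testing.assert_array_equal(m.confusion, np.eye(3, dtype=int) * 2)

    def test_constant_prediction_on_balanced_classes(self):
        y = np.repeat([0, 1, 2], 10)
        pred = np.zeros(30, dtype=int)
        m = _metrics_from_predictions(y, pred, np.array(["i", "l", "b"]))
        assert m.accuracy == pytest.approx(1 / 3)

    def test_confusion_matrix_matches_hand_count(self):
        y_true = np.array([0, 0, 1, 1, 2, 2, 2])
        y_pred = np.array([0, 1, 1, 1, 0, 2, 2])
        m = _metrics_from_predictions(y_true, y_pred, np.array(["a", "b", "c"]))
        np.testing.assert_array_equal(
            m.confusion, [[1, 1, 0], [0, 2, 0], [1, 0, 2]]
        )
        assert m.confusion.trace() == 5
        assert m.accuracy == pytest.approx(5 / 7)

    def test_unknown_label_rejected(self, rng, small_dataset):
        enc = build_encoder(EncoderConfig(kind="mlp"), rng)
        head, _ = train_probe(enc, small_dataset, ProbeConfig(epochs=1))
        alien = build_feature_matrix(small_dataset.values[:5], labels=["sprint"] * 5)
        with pytest.raises(ValueError, match="sprint"):
            evaluate(head, enc, alien)


class TestBaselineTransfer:
    def test_random_init_fallback_runs_end_to_end(self, small_dataset):
        folds, mean = baseline_transfer(
            small_dataset, EncoderConfig(kind="mlp"), ProbeConfig(epochs=10, seed=0)
        )
        assert len(folds) == 5
        assert 0.0 <= mean.accuracy <= 1.0

    def test_report_schema_matches_evaluate(self, small_dataset):
        _, mean = baseline_transfer(
            small_dataset, EncoderConfig(kind="mlp"), ProbeConfig(epochs=5, seed=0)
        )
        assert isinstance(mean, ClassificationMetrics)
        assert set(mean.to_dict()) == {
            "accuracy", "precision", "recall", "f1", "classes", "confusion", "per_class",
        }
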