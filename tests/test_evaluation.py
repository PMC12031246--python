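"""Fold hygiene, confusion-matrix metrics and the evaluation protocol."""

import numpy as np
import pytest

from dolphinet import (
    ConfusionMatrix,
    TrainConfig,
    confusion_from_predictions,
    kernel_size_sweep,
    make_folds,
    metrics_from_confusion,
    run_cross_validation,
)
from dolphinet.spectrogram import SpectrogramImage
from dolphinet.audio_io import VocalizationClass


class LabelReadoutStub:
    """Truth-echo classifier: the label is painted into pixel (0, 0)."""

    def fit(self, x, y, train_config=None):
        return self

    def predict(self, x):
        return np.round(np.asarray(x)[:, 0, 0, 0] * 10).astype(int)


def painted_images(labels):
    rng = np.random.default_rng(0)
    out = rng.random((len(labels), 8, 8, 1)).astype(np.float32) * 0.04
    out[:, 0, 0, 0] = np.asarray(labels) / 10.0
    return out


class TestMakeFolds:
    def test_equal_fold_sizes(self):
        folds = make_folds(100, n_folds=10, seed=0)
        assert all(f.test_indices.size == 10 for f in folds)

    def test_partition_and_disjointness(self):
        folds = make_folds(103, n_folds=10, seed=1)
        all_test = np.concatenate([f.test_indices for f in folds])
        assert np.array_equal(np.sort(all_test), np.arange(103))
        for f in folds:
            assert np.intersect1d(f.train_indices, f.test_indices).size == 0
            assert f.train_indices.size + f.test_indices.size == 103

    def test_stratified_minority_class_spread(self):
        # 420 items of a minority class among 4200: stratification puts 42 in
        # each test fold
        labels = np.array([0] * 3780 + [1] * 420)
        folds = make_folds(4200, n_folds=10, seed=2, stratify_labels=labels)
        for f in folds:
            assert (labels[f.test_indices] == 1).sum() == 42

    def test_more_folds_than_items_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, n_folds=10, seed=0)


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        cm = confusion_from_predictions([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        assert np.array_equal(cm.counts, np.eye(5, dtype=int))

    def test_hand_counted_example(self):
        cm = confusion_from_predictions([1, 1, 2], [1, 2, 2])
        assert cm.counts[1, 1] == 1
        assert cm.counts[1, 2] == 1
        assert cm.counts[2, 2] == 1
        assert cm.total == 3

    def test_row_normalization(self):
        cm = confusion_from_predictions([0, 0, 1, 1, 1], [0, 1, 1, 1, 0])
        normalized = cm.row_normalized()
        assert normalized[:2].sum(axis=1) == pytest.approx([1.0, 1.0])

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import confusion_matrix

        t = rng.integers(0, 5, 500)
        p = rng.integers(0, 5, 500)
        cm = confusion_from_predictions(t, p)
        assert np.array_equal(cm.counts, confusion_matrix(t, p, labels=range(5)))

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_from_predictions([0, 5], [0, 0])


class TestMetrics:
    def test_diagonal_matrix_all_hundred(self):
        report = metrics_from_confusion(ConfusionMatrix(np.eye(5, dtype=int) * 7))
        for metric in ("accuracy", "precision", "recall", "f1"):
            assert getattr(report, metric) == pytest.approx(np.full(5, 100.0))
        assert report.micro_accuracy == 100.0

    def test_two_class_hand_computation(self):
        report = metrics_from_confusion(ConfusionMatrix(np.array([[50, 10], [5, 35]])))
        assert report.precision[1] == pytest.approx(35 / 45 * 100, abs=0.05)
        assert report.recall[1] == pytest.approx(35 / 40 * 100, abs=0.05)
        assert report.f1[1] == pytest.approx(82.4, abs=0.05)
        assert report.accuracy[1] == pytest.approx(85 / 100 * 100)

    def test_absent_class_flagged_zero(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 10
        counts[1, 1] = 5
        report = metrics_from_confusion(ConfusionMatrix(counts))
        assert report.recall[3] == 0.0
        assert report.undefined["recall"][3]
        assert not report.undefined["recall"][0]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics_from_confusion(ConfusionMatrix(np.zeros((5, 5), dtype=int)))

    def test_agrees_with_per_item_counting_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            t = rng.integers(0, 5, n)
            p = rng.integers(0, 5, n)
            report = metrics_from_confusion(confusion_from_predictions(t, p))
            for c in range(5):
                tp = np.sum((t == c) & (p == c))
                fp = np.sum((t != c) & (p == c))
                fn = np.sum((t == c) & (p != c))
                tn = n - tp - fp - fn
                assert report.accuracy[c] == pytest.approx((tp + tn) / n * 100)
                expected_p = tp / (tp + fp) * 100 if tp + fp else 0.0
                expected_r = tp / (tp + fn) * 100 if tp + fn else 0.0
                assert report.precision[c] == pytest.approx(expected_p)
                assert report.recall[c] == pytest.approx(expected_r)
            assert report.micro_accuracy == pytest.approx(np.mean(t == p) * 100)

    def test_row_column_sums_identities(self, rng):
        t = rng.integers(0, 5, 300)
        p = rng.integers(0, 5, 300)
        cm = confusion_from_predictions(t, p)
        tp = np.diag(cm.counts)
        for c in range(5):
            assert tp[c] + (cm.counts[c].sum() - tp[c]) == cm.counts[c].sum()  # TP+FN
            assert tp[c] + (cm.counts[:, c].sum() - tp[c]) == cm.counts[:, c].sum()  # TP+FP


class TestCrossValidation:
    def test_truth_echo_stub_scores_hundred_everywhere(self):
        labels = np.tile(np.arange(5), 20)
        x = painted_images(labels)
        result = run_cross_validation(
            x, labels, n_folds=10, seed=0, classifier_factory=lambda s: LabelReadoutStub()
        )
        assert len(result.fold_reports) == 10
        for report in result.fold_reports:
            assert report.micro_accuracy == 100.0
            assert report.f1 == pytest.approx(np.full(5, 100.0))
        summary = result.summary()
        assert summary.loc["mean", "f1_mean"] == pytest.approx(100.0)
        assert summary.loc["mean", "f1_sd"] == 0.0  # constant metric -> SD 0
        assert np.allclose(result.mean_confusion(), np.eye(5))

    def test_no_leakage_between_train_and_test(self):
        labels = np.tile(np.arange(5), 10)
        x = painted_images(labels)
        seen = {"train": [], "test": []}

        class Recorder(LabelReadoutStub):
            def fit(self, xb, yb, train_config=None):
                seen["train"].append(xb.copy())
                return self

        result = run_cross_validation(
            x, labels, n_folds=5, seed=3, classifier_factory=lambda s: Recorder()
        )
        for split in result.fold_splits:
            assert np.intersect1d(split.train_indices, split.test_indices).size == 0
        all_test = np.concatenate([s.test_indices for s in result.fold_splits])
        assert np.array_equal(np.sort(all_test), np.arange(labels.size))

    def test_missing_class_in_fold_warns(self):
        labels = np.array([0] * 30 + [1] * 30 + [2] * 3)
        x = painted_images(labels)
        from dolphinet.model import ModelConfig

        with pytest.warns(UserWarning, match="absent"):
            run_cross_validation(
                x, labels, model_config=ModelConfig(input_shape=(8, 8, 1), n_classes=4),
                n_folds=3, seed=0, classifier_factory=lambda s: LabelReadoutStub(),
            )


class TestKernelSweep:
    def _binary_images(self, n):
        rng = np.random.default_rng(0)
        images, targets = [], []
        for i in range(n):
            klass = VocalizationClass.WHISTLE if i % 2 else VocalizationClass.NOISE
            pixels = rng.random((30, 40)) * 0.2
            if klass == VocalizationClass.WHISTLE:
                pixels[12:15, :] += 0.7  # horizontal contour
            images.append(
                SpectrogramImage(
                    np.clip(pixels, 0, 1), np.arange(40, dtype=float),
                    np.arange(30, dtype=float) + 1, klass,
                )
            )
            targets.append(int(klass == VocalizationClass.WHISTLE))
        return images, np.array(targets)

    def test_table_layout_and_internal_consistency(self):
        images, targets = self._binary_images(40)
        table, spread = kernel_size_sweep(
            images, targets, sizes=[3, 5, 7, 9, 11], seed=0,
            classifier_factory=lambda s: _PixelSumStub(),
        )
        assert table.shape == (5, 4)
        assert list(table.columns) == ["accuracy", "precision", "recall", "f1"]
        assert list(table.index) == [3, 5, 7, 9, 11]
        assert spread.shape == (4,)
        assert (spread >= 0).all()

    def test_invalid_size_rejected(self):
        images, targets = self._binary_images(10)
        with pytest.raises(ValueError, match="size"):
            kernel_size_sweep(images, targets, sizes=[3, 6])


class _PixelSumStub:
    """Threshold on mean intensity: separates the painted binary fixture."""

    def fit(self, x, y, train_config=None):
        means = x.mean(axis=(1, 2, 3))
        self.threshold = (means[y == 0].mean() + means[y == 1].mean()) / 2
        self.flip = means[y == 1].mean() < means[y == 0].mean()
        return self

    def predict(self, x):
        above = x.mean(axis=(1, 2, 3)) > self.threshold
        return (~above if self.flip else above).astype(int)
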