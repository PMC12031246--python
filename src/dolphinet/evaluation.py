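"""Cross-validation protocol, per-class metrics and the kernel-size sweep.

Metrics follow the multiclass one-vs-rest reading: for each class ``c`` the
confusion matrix collapses to TP/FP/FN/TN against all other classes, and

* per-class accuracy = (TP + TN) / N  (this is the only reading under which
  a multiclass table can report a distinct accuracy per class),
* precision = TP / (TP + FP), recall = TP / (TP + FN),
* F1 = harmonic mean of precision and recall.

Ratios with a zero denominator are reported as 0 and flagged, which keeps
mean +/- SD aggregation stable. Aggregates are the unweighted (macro) mean
over classes; the overall micro-accuracy trace(cm)/N is reported alongside.
All percentages are on the 0-100 scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold


from .datasets import apply_policy_filter, images_to_array
from .edge_filter import DEFAULT_POLICY, VALID_SIZES, FilterPolicy
from .model import CNNClassifier, ModelConfig, TrainConfig, simplified_config
from .spectrogram import SpectrogramImage

__all__ = [
    "FoldSplit",
    "ConfusionMatrix",
    "MetricsReport",
    "CVResult",
    "make_folds",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "run_cross_validation",
    "kernel_size_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldSplit:
    """One train/test partition of the dataset indices."""

    fold_id: int
    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError(f"fold {self.fold_id}: train and test indices overlap")


@dataclass
class ConfusionMatrix:
    """Integer counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def row_normalized(self) -> np.ndarray:
        """Rows rescaled to sum to 1 (empty rows stay zero)."""
        counts = self.counts.astype(np.float64)
        sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, counts / sums, 0.0)
        return out


def make_folds(
    n_items: int,
    n_folds: int = 10,
    seed: int = 0,
    stratify_labels: Sequence[int] | np.ndarray | None = None,
) -> list[FoldSplit]:
    """Seeded shuffled k-fold partition, stratified when labels are given.

    Test folds have size ``floor(N/k)`` or ``ceil(N/k)`` and tile all
    indices exactly once.
    """
    if n_folds > n_items:
        raise ValueError(f"cannot make {n_folds} folds from {n_items} items")
    indices = np.arange(n_items)
    if stratify_labels is not None:
        labels = np.asarray(stratify_labels)
        if labels.shape[0] != n_items:
            raise ValueError("stratify_labels length does not match n_items")
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(indices, labels)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(indices)
    return [
        FoldSplit(i, train.copy(), test.copy()) for i, (train, test) in enumerate(split_iter)
    ]


def confusion_from_predictions(
    true_labels: Sequence[int] | np.ndarray,
    predicted_labels: Sequence[int] | np.ndarray,
    n_classes: int = 5,
) -> ConfusionMatrix:
    """Count matrix ``counts[i, j] = #{true i, predicted j}``."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label sequences differ in length")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


@dataclass
class MetricsReport:
    """Per-class and aggregate metrics, in percent."""

    accuracy: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    undefined: dict[str, np.ndarray]  # metric -> boolean flags per class
    micro_accuracy: float

    @property
    def n_classes(self) -> int:
        return self.accuracy.size

    def macro(self, metric: str) -> float:
        """Unweighted mean of a per-class metric."""
        return float(np.mean(getattr(self, metric)))

    def macro_sd(self, metric: str) -> float:
        values = getattr(self, metric)
        return float(np.std(values, ddof=1)) if values.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "accuracy": self.accuracy,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
            },
            index=pd.Index(range(self.n_classes), name="class"),
        )
        frame.loc["mean"] = [self.macro(m) for m in ("accuracy", "precision", "recall", "f1")]
        return frame


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest per-class metrics from a confusion matrix (see module doc)."""
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def safe_ratio(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        undefined = den == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(undefined, 0.0, num / np.where(undefined, 1.0, den))
        return out, undefined

    precision, p_undef = safe_ratio(tp, tp + fp)
    recall, r_undef = safe_ratio(tp, tp + fn)
    f1, f_undef = safe_ratio(2.0 * precision * recall, precision + recall)
    accuracy = (tp + tn) / total
    return MetricsReport(
        accuracy=accuracy * 100.0,
        precision=precision * 100.0,
        recall=recall * 100.0,
        f1=f1 * 100.0,
        undefined={"precision": p_undef, "recall": r_undef, "f1": f_undef | p_undef | r_undef},
        micro_accuracy=float(np.trace(counts) / total * 100.0),
    )


@dataclass
class CVResult:
    """Everything a cross-validation run produces."""

    fold_reports: list[MetricsReport]
    fold_confusions: list[ConfusionMatrix]
    fold_splits: list[FoldSplit]

    def mean_confusion(self) -> np.ndarray:
        """Entrywise mean of the row-normalized per-fold confusion matrices."""
        return np.mean([cm.row_normalized() for cm in self.fold_confusions], axis=0)

    def summary(self) -> pd.DataFrame:
        """Per-class mean +/- SD over folds, plus macro and micro aggregates."""
        metrics = ("accuracy", "precision", "recall", "f1")
        rows = {}
        for metric in metrics:
            stack = np.stack([getattr(r, metric) for r in self.fold_reports])
            rows[f"{metric}_mean"] = stack.mean(axis=0)
            rows[f"{metric}_sd"] = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(stack.shape[1])
        frame = pd.DataFrame(rows, index=pd.Index(range(self.fold_reports[0].n_classes), name="class"))
        macro = {
            f"{metric}_mean": np.mean([r.macro(metric) for r in self.fold_reports])
            for metric in metrics
        }
        macro.update(
            {
                f"{metric}_sd": (
                    np.std([r.macro(metric) for r in self.fold_reports], ddof=1)
                    if len(self.fold_reports) > 1
                    else 0.0
                )
                for metric in metrics
            }
        )
        frame.loc["mean"] = pd.Series(macro)
        return frame

    def micro_accuracies(self) -> np.ndarray:
        return np.array([r.micro_accuracy for r in self.fold_reports])


def _default_factory(
    model_config: ModelConfig | None, train_config: TrainConfig | None
) -> Callable[[int], CNNClassifier]:
    def factory(seed: int) -> CNNClassifier:
        return CNNClassifier(model_config or ModelConfig(), seed=seed)

    return factory


def run_cross_validation(
    images: Sequence[SpectrogramImage] | np.ndarray,
    labels: Sequence[int] | np.ndarray | None = None,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    sobel_size: int = 7,
    n_folds: int = 10,
    seed: int = 0,
    policy: FilterPolicy = DEFAULT_POLICY,
    classifier_factory: Callable[[int], object] | None = None,
    prefiltered: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of the classifier.

    ``images`` may be :class:`SpectrogramImage` objects (labels default to
    their ``klass``; label-aware edge filtering with ``sobel_size`` is
    applied unless ``prefiltered``) or a ready (N, H, W, 1) array. Each fold
    trains a fresh classifier on the other ``n_folds - 1`` folds and
    evaluates on the held-out fold; train/test index disjointness is
    asserted. Folds missing a class are tolerated with a warning (the
    affected per-class metrics are flagged).
    """
    if isinstance(images, np.ndarray):
        x = images.astype(np.float32)
        if labels is None:
            raise ValueError("labels are required with array input")
    else:
        images = list(images)
        if labels is None:
            if any(img.klass is None for img in images):
                raise ValueError("unlabeled images: pass labels explicitly")
            labels = [int(img.klass) for img in images]
        if not prefiltered:
            images = apply_policy_filter(images, size=sobel_size, policy=policy)
        x = images_to_array(images)
    y = np.asarray(labels, dtype=np.int64)
    n_classes = (model_config or ModelConfig()).n_classes
    if np.unique(y).size < 2:
        raise ValueError("cross-validation needs at least two classes present")

    factory = classifier_factory or _default_factory(model_config, train_config)
    folds = make_folds(y.size, n_folds=n_folds, seed=seed, stratify_labels=y)
    reports: list[MetricsReport] = []
    confusions: list[ConfusionMatrix] = []
    for split in folds:
        assert np.intersect1d(split.train_indices, split.test_indices).size == 0
        test_classes = np.unique(y[split.test_indices])
        if test_classes.size < n_classes:
            warnings.warn(
                f"fold {split.fold_id}: classes "
                f"{sorted(set(range(n_classes)) - set(test_classes.tolist()))} absent "
                "from the test set; their metrics are flagged undefined",
                stacklevel=2,
            )
        clf = factory(seed + split.fold_id)
        clf.fit(x[split.train_indices], y[split.train_indices], train_config)
        predicted = np.asarray(clf.predict(x[split.test_indices]))
        cm = confusion_from_predictions(y[split.test_indices], predicted, n_classes)
        confusions.append(cm)
        reports.append(metrics_from_confusion(cm))
    return CVResult(reports, confusions, folds)


def kernel_size_sweep(
    images: Sequence[SpectrogramImage],
    binary_labels: Sequence[int] | np.ndarray,
    sizes: Sequence[int] = VALID_SIZES,
    split: tuple[float, float, float] = (0.65, 0.10, 0.25),
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    policy: FilterPolicy = DEFAULT_POLICY,
    classifier_factory: Callable[[int], object] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sensitivity of the simplified binary classifier to the Sobel size.

    For each kernel size the whistle-versus-rest dataset is filtered
    (label-aware, using each image's true multiclass label), split into
    train/validation/test fractions, and a simplified network is trained.
    Returns a table with one row per size (accuracy and positive-class
    precision/recall/F1, in percent) and the max-min spread per metric.
    """
    for size in sizes:
        if size not in VALID_SIZES:
            raise ValueError(f"kernel size {size} outside {VALID_SIZES}")
    if abs(sum(split) - 1.0) > 1e-9 or min(split) < 0:
        raise ValueError("split fractions must be non-negative and sum to 1")
    images = list(images)
    y = np.asarray(binary_labels, dtype=np.int64)
    if y.size != len(images):
        raise ValueError("binary_labels length does not match images")

    # stratified train+val / test split; the trainer carves out the
    # validation slice internally at val/(train+val)
    rng = np.random.default_rng(seed)
    test_idx, trainval_idx = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_test = int(round(split[2] * idx.size))
        test_idx.append(idx[:n_test])
        trainval_idx.append(idx[n_test:])
    test_idx = np.concatenate(test_idx)
    trainval_idx = np.concatenate(trainval_idx)

    mc = model_config or simplified_config(
        input_shape=(images[0].shape[0], images[0].shape[1], 1)
    )
    tc = train_config or TrainConfig()
    val_fraction = split[1] / (split[0] + split[1])
    tc = TrainConfig(
        learning_rate=tc.learning_rate,
        batch_size=tc.batch_size,
        max_epochs=tc.max_epochs,
        patience=tc.patience,
        val_fraction=val_fraction,
        seed=tc.seed,
    )

    rows = []
    for size in sizes:
        filtered = apply_policy_filter(images, size=size, policy=policy)
        x = images_to_array(filtered)
        if classifier_factory is not None:
            clf = classifier_factory(seed + size)
        else:
            clf = CNNClassifier(mc, seed=seed + size)
        clf.fit(x[trainval_idx], y[trainval_idx], tc)
        predicted = np.asarray(clf.predict(x[test_idx]))
        cm = confusion_from_predictions(y[test_idx], predicted, n_classes=2)
        report = metrics_from_confusion(cm)
        rows.append(
            {
                "kernel_size": size,
                "accuracy": report.micro_accuracy,
                "precision": report.precision[1],
                "recall": report.recall[1],
                "f1": report.f1[1],
            }
        )
        logger.info("kernel size %d: accuracy %.1f%%", size, report.micro_accuracy)
    table = pd.DataFrame(rows).set_index("kernel_size")
    spread = table.max(axis=0) - table.min(axis=0)
    spread.name = "max_min_spread"
    return table, spread
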