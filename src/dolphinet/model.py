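"""The spectrogram CNN and its training procedure.

The default architecture maps a 150x300 grayscale image through three
convolution + max-pooling stages (32, 64, 128 filters; 6x3 kernels, ReLU;
2x2 pooling) into a 128-unit dense layer and a 5-way softmax. A simplified
variant (two stages of 16 and 32 filters, 64 dense units, 2 classes) serves
the kernel-size sensitivity experiment.

Training minimizes categorical cross-entropy with Adam. The study states no
training hyperparameters, so the defaults here (learning rate 1e-3, batch
16, up to 30 epochs, early stopping on a 10 % validation slice) are the
package's own, exposed through :class:`TrainConfig`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .nn import (
    Adam,
    Conv2D,
    Dense,
    Flatten,
    MaxPool2D,
    ReLU,
    SequentialNet,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "CNNClassifier",
    "simplified_config",
    "build_model",
    "train_model",
    "predict",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters."""

    conv_filters: tuple[int, ...] = (32, 64, 128)
    conv_kernel: tuple[int, int] = (6, 3)  # (frequency, time)
    pool: tuple[int, int] = (2, 2)
    dense_units: int = 128
    n_classes: int = 5
    input_shape: tuple[int, int, int] = (150, 300, 1)

    def __post_init__(self) -> None:
        if len(self.conv_filters) < 1:
            raise ValueError("at least one convolutional stage is required")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    def spatial_dims(self) -> list[tuple[int, int]]:
        """Spatial size after each conv+pool stage (same-padded conv, floor pool)."""
        h, w = self.input_shape[:2]
        dims = []
        for _ in self.conv_filters:
            h, w = h // self.pool[0], w // self.pool[1]
            dims.append((h, w))
        return dims

    def flat_features(self) -> int:
        h, w = self.spatial_dims()[-1]
        return h * w * self.conv_filters[-1]


def simplified_config(input_shape: tuple[int, int, int] = (150, 300, 1)) -> ModelConfig:
    """The reduced architecture of the kernel-size sensitivity experiment:
    two convolutional stages of 16 and 32 filters and a 64-unit dense layer,
    for binary whistle-versus-rest recognition."""
    return ModelConfig(
        conv_filters=(16, 32), dense_units=64, n_classes=2, input_shape=input_shape
    )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (all package-chosen; none are prescribed)."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 30
    patience: int = 3
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning_rate, batch_size and max_epochs must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


class CNNClassifier:
    """Sequential CNN with a scikit-learn-flavoured fit/predict surface."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        self.seed = seed
        self.history: dict[str, list[float]] = {}
        rng = np.random.default_rng(seed)
        h, w, c = config.input_shape
        min_h, min_w = config.pool[0] ** len(config.conv_filters), config.pool[1] ** len(config.conv_filters)
        if h < min_h or w < min_w:
            raise ValueError(
                f"input {h}x{w} too small for {len(config.conv_filters)} pooling "
                f"stages; minimum is {min_h}x{min_w}"
            )
        layers = []
        in_ch = c
        for filters in config.conv_filters:
            layers += [Conv2D(in_ch, filters, config.conv_kernel, rng), ReLU(), MaxPool2D(config.pool)]
            in_ch = filters
        layers += [Flatten(), Dense(config.flat_features(), config.dense_units, rng), ReLU(),
                   Dense(config.dense_units, config.n_classes, rng)]
        self.net = SequentialNet(layers)

    # ------------------------------------------------------------------
    def _check_inputs(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4 or x.shape[1:] != self.config.input_shape:
            raise ValueError(
                f"images of shape {x.shape[1:]} do not match the model input "
                f"{self.config.input_shape}"
            )
        return x

    def predict_proba(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Row-normalized class probabilities, one row per image."""
        x = self._check_inputs(images)
        chunks = [
            softmax(self.net.forward(x[i : i + batch_size], train=False))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(chunks, axis=0).astype(np.float64)

    def predict(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Argmax labels; ties resolve to the lowest class index."""
        return np.argmax(self.predict_proba(images, batch_size), axis=1)

    # ------------------------------------------------------------------
    def fit(
        self,
        images: np.ndarray,
        labels: Sequence[int] | np.ndarray,
        train_config: TrainConfig | None = None,
    ) -> "CNNClassifier":
        """Train with Adam on softmax cross-entropy.

        A ``val_fraction`` slice (seeded shuffle) is held out for early
        stopping on validation loss; the best-validation weights are
        restored. With ``val_fraction=0`` training runs all epochs.
        """
        cfg = train_config or TrainConfig()
        x = self._check_inputs(images)
        y = np.asarray(labels, dtype=np.int64)
        if x.shape[0] == 0:
            raise ValueError("empty training set")
        if y.shape[0] != x.shape[0]:
            raise ValueError("images and labels differ in length")
        if y.min() < 0 or y.max() >= self.config.n_classes:
            raise ValueError("labels outside the configured class range")
        if np.unique(y).size < 2:
            raise ValueError(
                "training set contains a single class; softmax cross-entropy is degenerate"
            )

        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(x.shape[0])
        n_val = int(round(cfg.val_fraction * x.shape[0]))
        val_idx, train_idx = order[:n_val], order[n_val:]
        if train_idx.size == 0:
            raise ValueError("validation split leaves no training data")
        xt, yt = x[train_idx], y[train_idx]
        xv, yv = x[val_idx], y[val_idx]
        eye = np.eye(self.config.n_classes, dtype=np.float32)

        optimizer = Adam(self.net.parameters, lr=cfg.learning_rate)
        history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
        best_val = np.inf
        best_weights = self.net.get_weights()
        stall = 0
        for _ in range(cfg.max_epochs):
            perm = rng.permutation(xt.shape[0])
            losses, hits, seen = [], 0, 0
            for i in range(0, xt.shape[0], cfg.batch_size):
                idx = perm[i : i + cfg.batch_size]
                xb, yb = xt[idx], yt[idx]
                logits = self.net.forward(xb, train=True)
                loss, dlogits = softmax_cross_entropy(logits, eye[yb])
                self.net.backward(dlogits)
                optimizer.step(self.net.gradients)
                losses.append(loss * xb.shape[0])
                hits += int((np.argmax(logits, axis=1) == yb).sum())
                seen += xb.shape[0]
            history["loss"].append(sum(losses) / seen)
            history["accuracy"].append(hits / seen)

            if xv.shape[0] > 0:
                val_logits = np.concatenate(
                    [self.net.forward(xv[i : i + cfg.batch_size], train=False)
                     for i in range(0, xv.shape[0], cfg.batch_size)]
                )
                val_loss, _ = softmax_cross_entropy(val_logits, eye[yv])
                history["val_loss"].append(val_loss)
                history["val_accuracy"].append(
                    float((np.argmax(val_logits, axis=1) == yv).mean())
                )
                if val_loss < best_val - 1e-6:
                    best_val, stall = val_loss, 0
                    best_weights = self.net.get_weights()
                else:
                    stall += 1
                    if stall > cfg.patience:
                        break
        if xv.shape[0] > 0:
            self.net.set_weights(best_weights)
        self.history = history
        return self

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights (npz) plus a JSON architecture manifest alongside."""
        path = Path(path)
        weights = {f"w{i}": w for i, w in enumerate(self.net.get_weights())}
        np.savez(path.with_suffix(".npz"), **weights)
        manifest = {"model_config": asdict(self.config), "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CNNClassifier":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        mc = manifest["model_config"]
        config = ModelConfig(
            conv_filters=tuple(mc["conv_filters"]),
            conv_kernel=tuple(mc["conv_kernel"]),
            pool=tuple(mc["pool"]),
            dense_units=mc["dense_units"],
            n_classes=mc["n_classes"],
            input_shape=tuple(mc["input_shape"]),
        )
        clf = cls(config, seed=manifest.get("seed", 0))
        with np.load(path.with_suffix(".npz")) as data:
            clf.net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        return clf


def build_model(config: ModelConfig | None = None, seed: int = 0) -> CNNClassifier:
    """Instantiate an untrained classifier (seeded He initialization)."""
    return CNNClassifier(config or ModelConfig(), seed=seed)


def train_model(
    classifier: CNNClassifier,
    images: np.ndarray,
    labels: np.ndarray,
    train_config: TrainConfig | None = None,
) -> tuple[CNNClassifier, dict[str, list[float]]]:
    """Functional wrapper: fit and return (classifier, per-epoch history)."""
    classifier.fit(images, labels, train_config)
    return classifier, classifier.history


def predict(classifier: CNNClassifier, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (lowest-index tie-break)."""
    probs = classifier.predict_proba(images)
    return probs, np.argmax(probs, axis=1)
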