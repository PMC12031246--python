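"""Synthetic image datasets for training and evaluating the classifier.

Each example is produced by the full pipeline: a seeded 0.8 s scene with one
vocalization (or pure noise) is rendered at 192 kHz, min-max normalized,
segmented around its annotation, turned into a 300x150 band-limited
spectrogram, and optionally edge-filtered with the class policy. Event
parameters are drawn from the class-typical ranges of
:mod:`dolphinet.synthetic`, so classes are separable by construction
(whistle contours versus pulse trains differing in inter-click interval and
centre frequency).
"""

from __future__ import annotations

import numpy as np

from .audio_io import AudioRecording, VocalizationClass, minmax_normalize
from .edge_filter import DEFAULT_POLICY, FilterPolicy, filter_for_class
from .segmentation import Segment, segment_event
from .spectrogram import SpectrogramImage, SpectrogramParams, compute_spectrogram
from .synthetic import SceneConfig, default_event, render_scene

__all__ = [
    "make_class_image",
    "make_multiclass_dataset",
    "make_binary_whistle_dataset",
    "apply_policy_filter",
    "images_to_array",
]

_SCENE_S = 0.8


def make_class_image(
    klass: VocalizationClass | int,
    seed: int,
    sample_rate: int = 192_000,
    snr_db: float | None = None,
    params: SpectrogramParams | None = None,
) -> SpectrogramImage:
    """One labeled spectrogram image produced by the full pipeline."""
    klass = VocalizationClass(klass)
    rng = np.random.default_rng(seed)
    events = []
    if klass != VocalizationClass.NOISE:
        duration = float(rng.uniform(0.45, 0.75))
        onset = float(rng.uniform(0.0, _SCENE_S - duration))
        snr = float(rng.uniform(8.0, 18.0)) if snr_db is None else snr_db
        events.append(default_event(klass, onset, duration, snr, rng=rng))
    config = SceneConfig(
        duration=_SCENE_S,
        sample_rate=sample_rate,
        seed=int(rng.integers(2**31)),
        events=events,
    )
    scene, labels = render_scene(config)
    recording = AudioRecording(minmax_normalize(scene), sample_rate, source_path=f"synthetic-{seed}")
    if labels:
        segment = segment_event(labels[0], recording)[0]
    else:  # noise scene: the whole window
        segment = Segment(recording.samples, klass, recording.source_path, 0.0, sample_rate)
    return compute_spectrogram(segment, params)


def make_multiclass_dataset(
    n_per_class: int,
    seed: int = 0,
    classes: tuple[VocalizationClass, ...] = tuple(VocalizationClass),
    sample_rate: int = 192_000,
) -> tuple[list[SpectrogramImage], np.ndarray]:
    """``n_per_class`` images for each requested class, deterministically seeded."""
    rng = np.random.default_rng(seed)
    images: list[SpectrogramImage] = []
    labels: list[int] = []
    for klass in classes:
        for _ in range(n_per_class):
            images.append(make_class_image(klass, int(rng.integers(2**31)), sample_rate))
            labels.append(int(klass))
    return images, np.array(labels, dtype=np.int64)


def make_binary_whistle_dataset(
    n_positive: int,
    n_negative: int,
    seed: int = 0,
    sample_rate: int = 192_000,
) -> tuple[list[SpectrogramImage], np.ndarray]:
    """Whistle-versus-rest dataset for the kernel-size experiment.

    Positives are whistles; negatives are an even mixture of ambient noise
    and the three impulsive vocalization types. The returned images keep
    their true multiclass label (needed for label-aware filtering); the
    second return value is the binary target (1 = whistle).
    """
    rng = np.random.default_rng(seed)
    images: list[SpectrogramImage] = []
    targets: list[int] = []
    for _ in range(n_positive):
        images.append(
            make_class_image(VocalizationClass.WHISTLE, int(rng.integers(2**31)), sample_rate)
        )
        targets.append(1)
    negatives = [
        VocalizationClass.NOISE,
        VocalizationClass.ECHOLOCATION_CLICK,
        VocalizationClass.BURST_PULSE,
        VocalizationClass.FEEDING_BUZZ,
    ]
    for i in range(n_negative):
        klass = negatives[i % len(negatives)]
        images.append(make_class_image(klass, int(rng.integers(2**31)), sample_rate))
        targets.append(0)
    return images, np.array(targets, dtype=np.int64)


def apply_policy_filter(
    images: list[SpectrogramImage],
    size: int = 7,
    policy: FilterPolicy = DEFAULT_POLICY,
) -> list[SpectrogramImage]:
    """Label-aware directional filtering of every image (training mode)."""
    return [filter_for_class(img, size=size, policy=policy) for img in images]


def images_to_array(images: list[SpectrogramImage]) -> np.ndarray:
    """Stack images into an (N, H, W, 1) float32 batch for the CNN."""
    return np.stack([img.pixels for img in images]).astype(np.float32)[..., None]
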