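"""Label-guided segmentation of recordings into fixed 0.8 s windows.

Every training example is a window of exactly ``round(0.8 * fs)`` samples.
An annotated event shorter than the window yields one window centred on the
event midpoint (shifted inward at file boundaries, never zero-padded, so the
window always contains real recording context). A longer event is tiled with
50 %-overlapping windows; the last window is right-aligned to the event end
so the union of windows covers the event exactly.

Noise examples (class 0) are windows drawn uniformly at random from the
annotation-free parts of a recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .audio_io import AnnotationEvent, AudioRecording, VocalizationClass

__all__ = ["Segment", "segment_event", "sample_noise_segments", "write_manifest"]

DEFAULT_WINDOW_S = 0.8
DEFAULT_OVERLAP = 0.5

#: Band edge the spectrogram stage needs; used only to warn on narrowband audio.
_REQUIRED_BANDWIDTH_HZ = 96_000.0

@dataclass
class Segment:
    """One fixed-length window with its class label and provenance."""

    samples: np.ndarray
    klass: VocalizationClass
    recording_id: str
    start: float  # seconds from recording start
    sample_rate: int

    @property
    def end(self) -> float:
        return self.start + self.samples.size / self.sample_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

def _window_samples(sample_rate: int, window_s: float) -> int:
    return int(round(window_s * sample_rate))

def segment_starts(
    start: float, end: float, window_s: float = DEFAULT_WINDOW_S, overlap_fraction: float = DEFAULT_OVERLAP
) -> list[float]:
    """Window start times tiling the interval ``[start, end]``.

    For duration ``d <= window`` this is the single centred window
    ``[mid - w/2, mid + w/2]`` (not yet clamped to the recording). For
    ``d > window`` the count law is ``n = ceil((d - w) / hop) + 1`` with
    ``hop = w * (1 - overlap)``; the first ``n - 1`` windows advance by the
    hop from ``start`` and the last is right-aligned to ``end``.
    """
    if not 0.0 < overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in (0, 1)")
    d = end - start
    if d <= window_s:
        mid = 0.5 * (start + end)
        return [mid - window_s / 2.0]
    hop = window_s * (1.0 - overlap_fraction)
    n = ceil((d - window_s) / hop - 1e-12) + 1
    starts = [start + i * hop for i in range(n - 1)]
    starts.append(end - window_s)
    return starts

def _extract(
    recording: AudioRecording, start_s: float, window_s: float, klass: VocalizationClass
) -> Segment:
    """Cut one window, shifting inward at recording boundaries."""
    win = _window_samples(recording.sample_rate, window_s)
    max_start = recording.samples.size - win
    i0 = int(round(start_s * recording.sample_rate))
    i0 = min(max(i0, 0), max_start)
    return Segment(
        samples=recording.samples[i0 : i0 + win],
        klass=klass,
        recording_id=recording.source_path,
        start=i0 / recording.sample_rate,
        sample_rate=recording.sample_rate,
    )

def segment_event(
    event: AnnotationEvent,
    recording: AudioRecording,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> list[Segment]:
    """Windows covering one annotated event (see module docstring).

    Raises if the recording is shorter than the window or the event lies
    outside it. Warns once when the recording bandwidth cannot reach the
    96 kHz analysis band edge.
    """
    win = _window_samples(recording.sample_rate, window_s)
    if recording.samples.size < win:
        raise ValueError(
            f"recording {recording.source_path} is shorter ({recording.duration:.3f} s) "
            f"than the {window_s} s window"
        )
    if event.start > recording.duration or event.end > recording.duration + 1e-9:
        raise ValueError(
            f"event [{event.start:.3f}, {event.end:.3f}] s lies outside the "
            f"{recording.duration:.3f} s recording"
        )
    if recording.sample_rate / 2.0 < _REQUIRED_BANDWIDTH_HZ:
        warnings.warn(
            f"recording sampled at {recording.sample_rate} Hz cannot represent the "
            f"96 kHz band edge (Nyquist {recording.sample_rate / 2:.0f} Hz)",
            stacklevel=2,
        )
    starts = segment_starts(event.start, event.end, window_s, overlap_fraction)
    return [_extract(recording, s, window_s, event.klass) for s in starts]

def sample_noise_segments(
    recording: AudioRecording,
    events: Sequence[AnnotationEvent],
    count: int,
    seed: int,
    window_s: float = DEFAULT_WINDOW_S,
    guard_s: float = 0.0,
) -> list[Segment]:
    """Draw ``count`` class-0 windows disjoint from every annotated event.

    Windows are placed uniformly at random within the annotation-free gaps
    (events optionally widened by ``guard_s`` on both sides). When the
    recording does not contain enough annotation-free audio, fewer windows
    are returned with a warning.
    """
    win = _window_samples(recording.sample_rate, window_s)
    if recording.samples.size < win:
        raise ValueError("recording shorter than the window")
    rng = np.random.default_rng(seed)

    # merge event intervals (with guard) and take the complement
    merged: list[list[float]] = []
    for ev in sorted(events, key=lambda e: e.start):
        lo, hi = max(ev.start - guard_s, 0.0), min(ev.end + guard_s, recording.duration)
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    gaps: list[tuple[float, float]] = []
    cursor = 0.0
    for lo, hi in merged:
        if lo > cursor:
            gaps.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < recording.duration:
        gaps.append((cursor, recording.duration))

    usable = [(lo, hi) for lo, hi in gaps if hi - lo >= window_s]
    if not usable:
        warnings.warn("no annotation-free interval long enough for a noise window", stacklevel=2)
        return []
    slack = np.array([hi - lo - window_s for lo, hi in usable])
    weights = slack + window_s  # probability proportional to placeable mass
    weights = weights / weights.sum()

    segments: list[Segment] = []
    for _ in range(count):
        k = int(rng.choice(len(usable), p=weights))
        lo, hi = usable[k]
        start = float(rng.uniform(lo, hi - window_s))
        segments.append(_extract(recording, start, window_s, VocalizationClass.NOISE))
    if len(segments) < count:
        warnings.warn(
            f"only {len(segments)} of {count} requested noise windows available", stacklevel=2
        )
    return segments

def write_manifest(path: str | Path, segments: Sequence[Segment]) -> pd.DataFrame:
    """Persist a segment manifest (recording id, start, end, class) as CSV."""
    frame = pd.DataFrame(
        {
            "recording_id": [s.recording_id for s in segments],
            "start_s": [s.start for s in segments],
            "end_s": [s.end for s in segments],
            "class": [int(s.klass) for s in segments],
            "class_name": [s.klass.label for s in segments],
        }
    )
    frame.to_csv(path, index=False)
    return frame
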