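"""WAV and annotation I/O for passive-acoustic-monitoring recordings.

Recordings are 16-bit PCM WAV files (the study design samples at 192 kHz so
that the 3–96 kHz analysis band is fully represented). Annotations are
Audacity label tracks: tab-separated ``start<TAB>end<TAB>label`` lines in
seconds. Label strings are mapped onto the five vocalization classes through
a configurable alias table, since annotators rarely agree on spellings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.io import wavfile

__all__ = [
    "VocalizationClass",
    "AnnotationEvent",
    "AudioRecording",
    "DEFAULT_LABEL_ALIASES",
    "load_recording",
    "write_recording",
    "minmax_normalize",
    "read_label_track",
    "write_label_track",
]

logger = logging.getLogger(__name__)

#: Scale between float samples in [-1, 1) and 16-bit integers.
_PCM16_FULL_SCALE = 32768.0


class VocalizationClass(IntEnum):
    """The five classes of the multiclass problem.

    Class 0 is ambient noise (absence of vocalization); classes 1–4 are the
    four bottlenose-dolphin vocalization types.
    """

    NOISE = 0
    WHISTLE = 1
    ECHOLOCATION_CLICK = 2
    BURST_PULSE = 3
    FEEDING_BUZZ = 4

    @property
    def label(self) -> str:
        return self.name.lower()


#: Default mapping from label-track strings to classes (lower-cased keys).
DEFAULT_LABEL_ALIASES: dict[str, VocalizationClass] = {
    "noise": VocalizationClass.NOISE,
    "n": VocalizationClass.NOISE,
    "0": VocalizationClass.NOISE,
    "class 0": VocalizationClass.NOISE,
    "whistle": VocalizationClass.WHISTLE,
    "w": VocalizationClass.WHISTLE,
    "1": VocalizationClass.WHISTLE,
    "class 1": VocalizationClass.WHISTLE,
    "click": VocalizationClass.ECHOLOCATION_CLICK,
    "clicks": VocalizationClass.ECHOLOCATION_CLICK,
    "click train": VocalizationClass.ECHOLOCATION_CLICK,
    "echolocation_click": VocalizationClass.ECHOLOCATION_CLICK,
    "c": VocalizationClass.ECHOLOCATION_CLICK,
    "2": VocalizationClass.ECHOLOCATION_CLICK,
    "class 2": VocalizationClass.ECHOLOCATION_CLICK,
    "burst": VocalizationClass.BURST_PULSE,
    "burst pulse": VocalizationClass.BURST_PULSE,
    "burst_pulse": VocalizationClass.BURST_PULSE,
    "bp": VocalizationClass.BURST_PULSE,
    "3": VocalizationClass.BURST_PULSE,
    "class 3": VocalizationClass.BURST_PULSE,
    "buzz": VocalizationClass.FEEDING_BUZZ,
    "feeding buzz": VocalizationClass.FEEDING_BUZZ,
    "feeding_buzz": VocalizationClass.FEEDING_BUZZ,
    "fb": VocalizationClass.FEEDING_BUZZ,
    "4": VocalizationClass.FEEDING_BUZZ,
    "class 4": VocalizationClass.FEEDING_BUZZ,
}


@dataclass(frozen=True)
class AnnotationEvent:
    """One labeled vocalization interval, in seconds from recording start."""

    start: float
    end: float
    klass: VocalizationClass

    def __post_init__(self) -> None:
        if not 0.0 <= self.start < self.end:
            raise ValueError(
                f"annotation interval must satisfy 0 <= start < end, "
                f"got [{self.start}, {self.end}]"
            )
        object.__setattr__(self, "klass", VocalizationClass(self.klass))

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class AudioRecording:
    """A mono waveform with its sample rate.

    ``samples`` are real-valued; 16-bit PCM is mapped to [-1, 1) on load.
    """

    samples: np.ndarray
    sample_rate: int
    bit_depth: int = 16
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.size == 0:
            raise ValueError("recording contains no samples")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sample_rate


def load_recording(path: str | Path) -> AudioRecording:
    """Load a PCM WAV file as a mono :class:`AudioRecording`.

    Multi-channel audio is collapsed to mono by averaging (the study recorder
    is single-hydrophone, so stereo files are unexpected but tolerated).
    Integer PCM is scaled to [-1, 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        sample_rate, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"{path}: not a readable PCM WAV file ({exc})") from exc
    if data.size == 0:
        raise ValueError(f"{path}: WAV file contains no audio")

    if data.dtype == np.int16:
        bit_depth = 16
        samples = data.astype(np.float64) / _PCM16_FULL_SCALE
    elif data.dtype == np.int32:
        bit_depth = 32
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        bit_depth = 8
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        bit_depth = 8 * data.dtype.itemsize
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")

    if samples.ndim == 2:
        logger.info("%s: averaging %d channels to mono", path, samples.shape[1])
        samples = samples.mean(axis=1)

    return AudioRecording(samples, int(sample_rate), bit_depth, str(path))


def write_recording(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    """Write float samples in [-1, 1) as 16-bit PCM mono WAV.

    Quantization rounds to the nearest integer step, so a waveform produced
    by :func:`load_recording` round-trips bit-exactly.
    """
    samples = np.asarray(samples, dtype=np.float64)
    pcm = np.round(samples * _PCM16_FULL_SCALE)
    n_clipped = int(np.sum((pcm < -32768) | (pcm > 32767)))
    if n_clipped:
        logger.warning("%s: clipping %d samples at full scale", path, n_clipped)
    pcm = np.clip(pcm, -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), int(sample_rate), pcm)


def minmax_normalize(samples: Sequence[float] | np.ndarray) -> np.ndarray:
    """Affinely map a signal onto [0, 1]: ``(x - min) / (max - min)``.

    Applied once per recording before segmentation. The map is
    order-preserving and idempotent. A constant signal has zero range and is
    rejected rather than silently returning NaN.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot normalize an empty signal")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant signal (zero range)")
    return (x - lo) / (hi - lo)


def _normalize_alias_table(
    aliases: Mapping[str, VocalizationClass | int] | None,
) -> dict[str, VocalizationClass]:
    table = DEFAULT_LABEL_ALIASES if aliases is None else aliases
    return {k.strip().lower(): VocalizationClass(v) for k, v in table.items()}


def read_label_track(
    path: str | Path,
    aliases: Mapping[str, VocalizationClass | int] | None = None,
    strict: bool = False,
) -> list[AnnotationEvent]:
    """Parse an Audacity label track into sorted :class:`AnnotationEvent`s.

    Each line is ``start<TAB>end<TAB>label``. Unknown labels are reported
    (warning, or error when ``strict``); lines with ``end <= start`` are
    rejected with their line number.
    """
    table = _normalize_alias_table(aliases)
    events: list[AnnotationEvent] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected start<TAB>end<TAB>label")
        try:
            start, end = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable time field") from exc
        if end <= start:
            raise ValueError(f"{path}:{lineno}: end ({end}) <= start ({start})")
        key = parts[2].strip().lower()
        if key not in table:
            msg = f"{path}:{lineno}: unknown label {parts[2]!r}"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg + " (line skipped)", stacklevel=2)
            continue
        events.append(AnnotationEvent(start, end, table[key]))
    events.sort(key=lambda e: (e.start, e.end))
    return events


def write_label_track(path: str | Path, events: Iterable[AnnotationEvent]) -> None:
    """Write events as an Audacity label track (6-decimal seconds, LF, UTF-8)."""
    lines = [f"{e.start:.6f}\t{e.end:.6f}\t{e.klass.label}" for e in events]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
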