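"""Band-limited grayscale spectrogram images of fixed 300x150 geometry.

Each 0.8 s window becomes a time-frequency image of 300 columns (time) by
150 rows (frequency) with pixel values in [0, 1], restricted to the
3-96 kHz analysis band. At the native 192 kHz rate a Hann window of 2048
samples with a 512-sample hop tiles the 153,600-sample segment into exactly
300 frames (frame centres at ``(i + 1/2) * hop``), so no temporal resampling
is needed; the 993 FFT bins inside the band are linearly interpolated down
to 150 rows.

Pipeline: magnitude STFT -> dB -> clip to a fixed dynamic range below the
image maximum -> per-image min-max to [0, 1] -> band crop -> resize. Because
the min-max follows the dB map, scaling the waveform by any positive
constant leaves the image unchanged. A silent window has no contrast and is
rendered as a uniform 0.5 image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image
from scipy.signal.windows import hann

from .audio_io import VocalizationClass
from .segmentation import Segment

__all__ = ["SpectrogramParams", "SpectrogramImage", "compute_spectrogram"]


@dataclass
class SpectrogramParams:
    """STFT and image-geometry parameters.

    Defaults are chosen so that at 192 kHz the 0.8 s window maps natively to
    300 frames and the 3-96 kHz band to 150 rows.
    """

    window: int = 2048
    hop: int = 512
    dynamic_range_db: float = 80.0
    band_low_hz: float = 3_000.0
    band_high_hz: float = 96_000.0
    out_width: int = 300
    out_height: int = 150

    def __post_init__(self) -> None:
        if self.window <= 0 or self.hop <= 0:
            raise ValueError("window and hop must be positive")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.out_width < 2 or self.out_height < 2:
            raise ValueError("output geometry must be at least 2x2")


@dataclass
class SpectrogramImage:
    """A (height x width) grayscale time-frequency image in [0, 1].

    Row 0 is the lowest frequency; ``freq_axis`` holds the row-centre
    frequencies (strictly increasing) and ``time_axis`` the frame-centre
    times in seconds.
    """

    pixels: np.ndarray
    time_axis: np.ndarray
    freq_axis: np.ndarray
    klass: VocalizationClass | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.shape != (self.freq_axis.size, self.time_axis.size):
            raise ValueError("axis lengths do not match the pixel grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain NaN or Inf")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixels must lie in [0, 1]")
        if not np.all(np.diff(self.freq_axis) > 0):
            raise ValueError("freq_axis must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_png(self, path: str | Path) -> None:
        """Write as 8-bit grayscale PNG (low frequencies at the bottom)."""
        img = np.flipud(np.clip(self.pixels, 0.0, 1.0))
        Image.fromarray((img * 255).round().astype(np.uint8), mode="L").save(Path(path))

    def replace_pixels(self, pixels: np.ndarray) -> "SpectrogramImage":
        return SpectrogramImage(pixels, self.time_axis, self.freq_axis, self.klass)


def _frame(samples: np.ndarray, window: int, hop: int) -> tuple[np.ndarray, np.ndarray]:
    """Centred frames: frame i covers the slice centred at ``(i + 1/2) * hop``."""
    n = samples.size
    n_frames = max(n // hop, 1)
    half = window // 2
    padded = np.pad(samples, half, mode="reflect" if n > half else "edge")
    centers = (np.arange(n_frames) * hop + hop // 2).astype(int)
    idx = centers[:, None] + np.arange(window)[None, :]  # start = centre - half + pad offset
    return padded[idx], centers / 1.0


def _interp_rows(values: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Linear interpolation of ``values`` (src x cols) onto ``dst`` positions."""
    pos = np.interp(dst, src, np.arange(src.size))
    i0 = np.clip(np.floor(pos).astype(int), 0, src.size - 2)
    w = (pos - i0)[:, None]
    return values[i0] * (1.0 - w) + values[i0 + 1] * w


def compute_spectrogram(
    segment: Union[Segment, np.ndarray],
    params: SpectrogramParams | None = None,
    sample_rate: float | None = None,
    klass: VocalizationClass | None = None,
) -> SpectrogramImage:
    """Render one fixed-length window as a band-limited grayscale image.

    Accepts a :class:`~dolphinet.segmentation.Segment` (its label is carried
    onto the image) or a raw waveform plus ``sample_rate``. Sample rates
    whose Nyquist frequency lies below the upper band edge are tolerated
    with a warning; the band is capped at Nyquist.
    """
    params = params or SpectrogramParams()
    if isinstance(segment, Segment):
        samples = np.asarray(segment.samples, dtype=np.float64)
        fs = float(segment.sample_rate)
        klass = segment.klass if klass is None else klass
    else:
        if sample_rate is None:
            raise ValueError("sample_rate is required for raw waveform input")
        samples = np.asarray(segment, dtype=np.float64)
        fs = float(sample_rate)
    if samples.ndim != 1 or samples.size < 2:
        raise ValueError("segment must be a 1-D waveform of at least 2 samples")
    if not np.all(np.isfinite(samples)):
        raise ValueError("waveform contains NaN or Inf")

    band_high = params.band_high_hz
    if fs / 2.0 < band_high:
        warnings.warn(
            f"sample rate {fs:.0f} Hz gives Nyquist {fs / 2:.0f} Hz, below the "
            f"{band_high:.0f} Hz band edge; capping the band",
            stacklevel=2,
        )
        band_high = fs / 2.0
    if band_high <= params.band_low_hz:
        raise ValueError("usable band is empty at this sample rate")

    frames, centers = _frame(samples, params.window, params.hop)
    win = hann(params.window, sym=False)
    mags = np.abs(np.fft.rfft(frames * win, axis=1)).T  # (bins, frames)

    db = 20.0 * np.log10(mags + 1e-12)
    db = np.clip(db, db.max() - params.dynamic_range_db, db.max())
    span = db.max() - db.min()
    if span < 1e-9:
        image = np.full_like(db, 0.5)  # silent / constant window: no contrast
    else:
        image = (db - db.min()) / span

    bin_freqs = np.fft.rfftfreq(params.window, d=1.0 / fs)
    target_freqs = np.linspace(params.band_low_hz, band_high, params.out_height)
    image = _interp_rows(image, bin_freqs, target_freqs)

    frame_times = centers / fs
    if image.shape[1] != params.out_width:
        target_times = np.linspace(frame_times[0], frame_times[-1], params.out_width)
        image = _interp_rows(image.T, frame_times, target_times).T
        frame_times = target_times

    return SpectrogramImage(
        pixels=np.clip(image, 0.0, 1.0),
        time_axis=np.asarray(frame_times),
        freq_axis=target_freqs,
        klass=klass,
    )
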