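"""Directional extended-Sobel filtering of spectrogram images.

A Sobel kernel is the outer product of a binomial smoothing vector along one
axis and a smoothed central-difference vector along the other (the
*derivative axis*). On a spectrogram:

* a **time-derivative** kernel responds to structures that change along
  time — the vertical streaks of echolocation clicks, burst pulses and
  feeding buzzes — and annihilates anything constant in time (horizontal
  bands such as tonal machinery noise);
* a **frequency-derivative** kernel responds to structures that change
  along frequency — the horizontal contours of whistles — and annihilates
  broadband vertical streaks.

Terminology note: the classic names "horizontal/vertical Sobel" are
ambiguous between the derivative axis and the orientation of the detected
edges. Here kernels are named by their **derivative axis**. The class
policy applies the frequency-derivative kernel to whistles and noise (it
suppresses vertical interference and preserves the horizontal whistle
contour) and the time-derivative kernel to the three impulsive classes
(it deletes horizontal interference, keeping the vertical pulse streaks).

Filtered responses are rectified (absolute value) and min-max rescaled so
images stay in [0, 1] for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union, overload

import numpy as np
from scipy.ndimage import correlate

from .audio_io import VocalizationClass
from .spectrogram import SpectrogramImage

__all__ = [
    "Axis",
    "EdgeKernel",
    "FilterPolicy",
    "DEFAULT_POLICY",
    "DEFAULT_KERNEL_SIZE",
    "make_kernel",
    "apply_kernel",
    "filter_for_class",
]

VALID_SIZES = (3, 5, 7, 9, 11)
DEFAULT_KERNEL_SIZE = 7

#: Derivative-axis names: "time" differentiates along columns (image width),
#: "frequency" along rows (image height).
Axis = str
_AXES = ("time", "frequency")


def _binomial_row(size: int) -> np.ndarray:
    """Pascal-triangle row of length ``size`` (smoothing vector)."""
    row = np.array([1.0])
    for _ in range(size - 1):
        row = np.convolve(row, [1.0, 1.0])
    return row


def _derivative_vector(size: int) -> np.ndarray:
    """[1, 0, -1] smoothed by ``size - 3`` convolutions with [1, 1]."""
    vec = np.array([1.0, 0.0, -1.0])
    for _ in range(size - 3):
        vec = np.convolve(vec, [1.0, 1.0])
    return vec


@dataclass(frozen=True)
class EdgeKernel:
    """A separable directional derivative kernel.

    ``weights`` is the outer product of a binomial smoothing vector along
    the non-derivative axis and a smoothed central difference along the
    derivative axis; it sums to zero and is antisymmetric under reflection
    along the derivative axis.
    """

    size: int
    derivative_axis: Axis
    weights: np.ndarray

    def transpose(self) -> "EdgeKernel":
        """Swap the derivative axis; the weight matrix is transposed."""
        other = "frequency" if self.derivative_axis == "time" else "time"
        return EdgeKernel(self.size, other, self.weights.T.copy())


def make_kernel(size: int, derivative_axis: Axis) -> EdgeKernel:
    """Build the extended Sobel kernel of odd ``size`` in {3, 5, 7, 9, 11}.

    With ``derivative_axis="time"`` and size 3 this is the canonical 3x3
    Sobel: columns proportional to [1, 0, -1] scaled by rows [1, 2, 1].
    """
    if size not in VALID_SIZES:
        raise ValueError(f"kernel size must be odd and in {VALID_SIZES}, got {size}")
    if derivative_axis not in _AXES:
        raise ValueError(f"derivative_axis must be one of {_AXES}")
    smooth = _binomial_row(size)
    deriv = _derivative_vector(size)
    if derivative_axis == "time":  # differentiate along columns
        weights = np.outer(smooth, deriv)
    else:  # differentiate along rows (frequency)
        weights = np.outer(deriv, smooth)
    return EdgeKernel(size, derivative_axis, weights)


@overload
def apply_kernel(image: np.ndarray, kernel: EdgeKernel) -> np.ndarray: ...
@overload
def apply_kernel(image: SpectrogramImage, kernel: EdgeKernel) -> SpectrogramImage: ...


def apply_kernel(image, kernel):
    """Cross-correlate with reflect padding, rectify and rescale to [0, 1].

    Output has the same shape as the input. An image with no edge response
    (e.g. a constant image) degenerates to a uniform 0.5 after rescaling,
    matching the silent-spectrogram convention.
    """
    if isinstance(image, SpectrogramImage):
        return image.replace_pixels(apply_kernel(image.pixels, kernel))
    pixels = np.asarray(image, dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("image must be 2-D")
    if min(pixels.shape) < kernel.size:
        raise ValueError(
            f"image {pixels.shape} smaller than the {kernel.size}x{kernel.size} kernel"
        )
    response = np.abs(correlate(pixels, kernel.weights, mode="reflect"))
    peak = response.max()
    if peak < 1e-12:
        return np.full_like(response, 0.5)
    return response / peak


@dataclass(frozen=True)
class FilterPolicy:
    """Class -> derivative-axis mapping for label-aware filtering."""

    mapping: Mapping[VocalizationClass, Axis]

    def __post_init__(self) -> None:
        for klass, axis in self.mapping.items():
            VocalizationClass(klass)
            if axis not in _AXES:
                raise ValueError(f"invalid axis {axis!r} for class {klass}")

    def axis_for(self, klass: VocalizationClass | int) -> Axis:
        return self.mapping[VocalizationClass(klass)]


#: The study policy: whistles and noise get the frequency-derivative
#: ("vertical") filter; the three impulsive classes get the time-derivative
#: ("horizontal") filter.
DEFAULT_POLICY = FilterPolicy(
    {
        VocalizationClass.NOISE: "frequency",
        VocalizationClass.WHISTLE: "frequency",
        VocalizationClass.ECHOLOCATION_CLICK: "time",
        VocalizationClass.BURST_PULSE: "time",
        VocalizationClass.FEEDING_BUZZ: "time",
    }
)


def filter_for_class(
    image: Union[np.ndarray, SpectrogramImage],
    klass: VocalizationClass | int | None = None,
    size: int = DEFAULT_KERNEL_SIZE,
    policy: FilterPolicy = DEFAULT_POLICY,
    direction: Axis | None = None,
):
    """Apply the class-appropriate directional kernel.

    In training/evaluation the true label selects the direction via
    ``policy``. At deployment the label is unknown; pass ``direction``
    explicitly ("time" or "frequency"). With neither a label nor a
    direction there is no defensible default and an error is raised.
    """
    if direction is None:
        if klass is None and isinstance(image, SpectrogramImage):
            klass = image.klass
        if klass is None:
            raise ValueError(
                "filter direction is label-dependent: supply klass (training mode) "
                "or an explicit direction override (deployment mode)"
            )
        direction = policy.axis_for(klass)
    return apply_kernel(image, make_kernel(size, direction))
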