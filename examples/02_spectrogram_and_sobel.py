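"""From a labeled event to a band-limited spectrogram and its Sobel filter.

Generates one whistle and one feeding-buzz image through the full pipeline
(scene -> normalization -> 0.8 s segment -> 300x150 spectrogram in the
3-96 kHz band), applies the class policy (frequency-derivative kernel for
the whistle, time-derivative for the buzz) and saves PNGs.
"""

from pathlib import Path

import numpy as np

from dolphinet import VocalizationClass, filter_for_class, make_class_image

out = Path("scratch_example_output")
out.mkdir(exist_ok=True)

for klass in (VocalizationClass.WHISTLE, VocalizationClass.FEEDING_BUZZ):
    image = make_class_image(klass, seed=7)
    filtered = filter_for_class(image, size=7)
    image.to_png(out / f"{klass.label}_raw.png")
    filtered.to_png(out / f"{klass.label}_sobel7.png")
    peak_row = int(image.pixels.mean(axis=1).argmax())
    print(
        f"{klass.label:12s} image {image.shape}, brightest row at "
        f"{image.freq_axis[peak_row]/1000:5.1f} kHz, "
        f"filtered mean intensity {filtered.pixels.mean():.3f}"
    )

print(
    "\nThe whistle's energy sits in its contour band (< 30 kHz); the buzz's\n"
    "brightest row is its pulse band. The *_sobel7.png images keep only the\n"
    "structures oriented along each class's characteristic direction."
)
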