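# Methods

`dolphinet` implements a pipeline for classifying bottlenose-dolphin
(*Tursiops truncatus*) vocalizations in passive-acoustic-monitoring (PAM)
recordings into five classes — ambient noise (0), whistles (1),
echolocation clicks (2), burst pulse sounds (3) and feeding buzzes (4) —
from fixed-geometry spectrogram images, with class-conditional directional
Sobel preprocessing and a small convolutional network, evaluated by
stratified 10-fold cross-validation. This note records the model, its
assumptions, the tunable parameters, and the design choices made where the
design was genuinely open.

## Pipeline

1. **Normalization.** Each recording (16-bit PCM WAV, nominally 192 kHz) is
   min–max normalized to [0, 1] once per file. This leaves a 0.5 DC offset
   on bipolar audio; it is harmless because the spectrogram band starts at
   3 kHz, far above DC.
2. **Segmentation.** Every labeled event becomes one or more windows of
   exactly `round(0.8 s × fs)` samples. Events shorter than 0.8 s yield one
   window centred on the event midpoint, shifted inward at file boundaries
   (real recording context, never zero padding). Longer events are tiled
   with 50 %-overlapping windows, `n = ceil((d − w)/(w/2)) + 1`, the first
   `n − 1` advancing by the 0.4 s hop from the event start and the last
   right-aligned to the event end so that the union of windows covers the
   event exactly. Noise (class 0) windows are drawn uniformly at random
   from annotation-free audio, seeded; an optional guard band around events
   (default 0 s) can exclude borderline audio.
3. **Spectrogram.** Magnitude STFT → dB → clip to an 80 dB dynamic range
   below the image maximum → per-image min–max to [0, 1] → crop to the
   3–96 kHz band → linear interpolation to 150 rows × 300 columns
   (frequency × time; row 0 is the lowest frequency). With a 2048-sample
   Hann window and 512-sample hop, the 153,600-sample window tiles into
   exactly 300 frames (frame centres at `(i + ½)·hop`), so no temporal
   resampling occurs at the native rate. The band limit is implemented as
   spectrogram cropping rather than time-domain filtering; for an image
   consumed by a classifier the two are equivalent. Because the min–max
   follows the dB map, the image is invariant to positive amplitude
   scaling. A silent window has no contrast and is defined to be uniform
   0.5. Lower sample rates are tolerated with a warning and a band capped
   at Nyquist.
4. **Directional Sobel filtering.** The extended Sobel kernel of odd size
   `k ∈ {3, 5, 7, 9, 11}` is the outer product of a binomial (Pascal-row)
   smoothing vector and the smoothed central difference
   `[1, 0, −1] ∗ [1, 1]^(k−3)`. Kernels are named by their **derivative
   axis**: the frequency-derivative kernel responds to structure that
   changes along frequency (whistle contours) and annihilates broadband
   vertical streaks; the time-derivative kernel does the converse. The
   class policy applies the frequency-derivative kernel to whistles and
   noise and the time-derivative kernel to the three impulsive classes.
   This naming is deliberate — "horizontal/vertical Sobel" is ambiguous
   between the derivative axis and the orientation of the detected edges.
   Responses are rectified (absolute value) and min–max rescaled to keep
   the classifier input in [0, 1]; correlation uses reflect padding so the
   image stays 150×300. Filtering is label-aware at training time; at
   deployment the label is unknown, so the API requires an explicit
   direction override (or none) rather than guessing.
5. **Classifier.** Three convolution stages of 32/64/128 filters (6×3
   kernels — 6 along frequency, 3 along time — ReLU, same padding), each
   followed by 2×2 max pooling with floor semantics
   (150×300 → 75×150 → 37×75 → 18×37), a 128-unit ReLU dense layer, and a
   5-way softmax output. The kernel-size experiment uses a simplified
   variant: two stages of 16/32 filters, a 64-unit dense layer, 2 classes.
6. **Evaluation.** Stratified seeded 10-fold cross-validation; per fold a
   fresh model trains on the other nine folds. Per-class metrics are
   one-vs-rest: accuracy (TP+TN)/N — the only reading under which a
   multiclass table can show a distinct accuracy per class — precision,
   recall, and F1. Zero-denominator ratios are reported as 0 with an
   `undefined` flag (rather than NaN) so mean ± SD aggregation stays
   stable. Aggregates are unweighted (macro) means over classes, with
   micro-accuracy trace(cm)/N alongside; per-fold aggregate
   precision/recall/F1 are macro-averaged. SDs use ddof = 1 across folds.

## The CNN engine

The network runs on a small numpy engine (`dolphinet.nn`): NHWC float32,
convolution evaluated as a sum over kernel offsets of channel-mixing BLAS
matrix products (with a single-gemm fast path for the one-channel input
layer), two-stage max pooling, softmax cross-entropy, and Adam
(β₁ = 0.9, β₂ = 0.999). Weights use He initialization from a seeded
generator, and batch order is drawn from the same generator, so training is
bit-reproducible for a fixed seed on a given platform. Max-pooling routes
the gradient to every entry tied at the window maximum (a valid subgradient
choice); prediction ties resolve to the lowest class index.

Training hyperparameters (none are prescribed by the protocol, all exposed
via `TrainConfig`): learning rate 1e-3, batch size 16, at most 30 epochs,
early stopping on a 10 % seeded validation slice with patience 3 and
best-weights restoration. The scripted experiments below override
`max_epochs` to 2, which the synthetic datasets saturate.

## Synthetic scenes

The study's pool recordings are not public, so a seeded simulator provides
labeled 192 kHz scenes. What it emulates:

* **whistles** — tonal calls synthesized by phase integration of a
  parametric contour (linear or sinusoidal between two frequencies inside
  the 3–96 kHz band), optional harmonics at −6 dB per order, Tukey-tapered;
* **click trains / burst pulses / feeding buzzes** — trains of
  Gaussian-windowed sinusoids whose −6 dB bandwidth sets the envelope
  width, placed at a mean inter-click interval (ICI) with uniform
  fractional jitter;
* **background** — an equal-power white + pink mixture at a configurable
  noise floor (default −45 dBFS RMS).

Class-typical defaults follow the qualitative field descriptions: feeding
buzzes use ICI 3–8 ms (< 10 ms) and centre frequencies 15–25 kHz
(< 30 kHz); echolocation clicks use ICI 80–160 ms and centres 55–75 kHz;
burst pulses use ICI 15–40 ms and centres 45–65 kHz (> 40 kHz for both);
whistle contours lie in 4–30 kHz. Exact distributions are the package's own
choice and are config-exposed. Event level is set by an in-band SNR — the
ratio of the event's RMS over its duration to the background RMS inside the
event's frequency band (no SNR convention is prescribed anywhere, so this
definition is documented here and tested). Dataset events draw SNR
uniformly from 8–18 dB.

What the simulator does **not** model: pool reverberation, propagation and
directionality, other species, vessel noise, overlapping vocalization
bouts, or recorder artifacts. Consequently, passing end-to-end tests shows
that the pipeline is implemented coherently and that the classes the
simulator defines are learnable through it — not that the classifier would
reach comparable performance on real recordings, where class overlap and
noise are far harsher.

## Scripted experiment sizes

Desk-scale runs are sized to finish in minutes on one CPU; the sizes are
fixed choices, not tuned quantities:

* multiclass separability: 200 images per class (1,000 total), label-aware
  size-7 filtering, stratified 80/20 holdout, 2 epochs. Expected held-out
  macro-F1 well above 85 %.
* kernel-size sweep: 400 whistle + 400 non-whistle images (negatives an
  even mixture of noise and the three impulsive classes), simplified
  network, 65/10/25 train/validation/test split, sizes 3–11, 2 epochs.
  Accuracy spread across sizes is expected within a few points.

The examples in `examples/` run the same flows at smaller sizes.

## Known limitations

* The deployment-time filter direction is label-dependent by construction;
  the API exposes both label-aware (training) and explicit-override
  (deployment) modes and takes no position on which a field system should
  use.
* Per-class one-vs-rest accuracy is optimistic for imbalanced data (TN
  dominates); the macro F1 and the confusion matrix are the more honest
  summaries.
* min–max normalization per recording means segment contrast depends on the
  loudest event in the file; per-segment spectrogram min–max largely
  removes this dependence downstream.
* The CNN engine is single-threaded numpy; it is adequate for the package's
  image geometry and dataset sizes but is not a general deep-learning
  runtime (no GPU, no augmentation, no transfer learning).
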