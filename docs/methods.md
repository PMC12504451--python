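# Methods

This note documents the models, the numerical choices, and the synthetic
study conditions behind `slecg`, in the order the pipeline runs.

## Signal model and units

All samples are held in millivolts.  WFDB inputs are converted using the
header gain/baseline; MAT and delimited inputs are assumed to be in mV
unless an explicit gain is passed (handheld-device exports often store
integer ADC counts at 1000 per mV).  A record is a list of equal-length,
equal-rate leads; positional lead naming follows the conventional
12-lead order I, II, III, aVR, aVL, aVF, V1–V6, with `SL` for a lone
single-lead channel.  The WFDB reader/writer supports format 16
(interleaved little-endian int16) only, which covers PTB-XL-style
exports; it is a minimal implementation, not a general WFDB library.

## Wavelet denoising

A level-1 discrete wavelet transform with the `bior3.1` biorthogonal
wavelet splits the signal into an approximation band (0 to fs/4) and a
detail band (fs/4 to fs/2).  The noise scale is estimated from the
finest detail band by the robust rule `sigma = MAD / 0.6745` — the
median absolute deviation about the median, scaled by the Gaussian
consistency constant.  (The constant 0.6745 belongs to the *median*
absolute deviation; pairing it with a mean-based deviation would be
internally inconsistent.)  Every detail band is then thresholded at the
universal threshold `T = sigma * sqrt(2 ln n)` with `n` the original
signal length, in one of the five standard modes (hard by default;
soft, garrote, greater, less available).  The approximation band passes
through untouched: at the 100 Hz working rate it carries 0–25 Hz, where
essentially all P-QRS-T energy lives.

Boundary handling uses the non-redundant periodization convention, so
an untouched decompose/reconstruct round-trip is exact (tested to 1e-8
relative error, measured ~1e-16) for any signal length; reconstruction
is truncated to the input length for odd-length signals.  Because both
`sigma` and `T` are homogeneous of degree 1 in the data, denoising is
scale-equivariant: `denoise(a*x) = a*denoise(x)`.

## Harmonization

Three mismatches separate clinical recorders from handheld devices:

* **Sampling rate** — Fourier-method resampling to a target rate
  (default 100 Hz, the clinical baseline), output length
  `round(n * target_fs / fs)`.
* **Amplitude scale** — division by `max|x|` followed by clipping into
  `[-1, 1]`.  Scaling by the absolute peak (not the signed maximum)
  keeps the waveform shape for negative-deflected leads and is
  well-defined before polarity correction has run; an identically-zero
  signal passes through.
* **Polarity** — a 4th-order Butterworth high-pass at 0.5 Hz, applied
  forward-backward for zero phase, removes wander and offset; the
  signal is inverted iff the sample of largest absolute amplitude in
  the filtered copy is negative.  0.5 Hz removes baseline wander
  without touching QRS energy; zero-phase filtering keeps the extreme
  sample aligned with the true deflection.  A tie between equal
  positive and negative extremes leaves the signal untouched (flip only
  on clear evidence).  The correction is idempotent and sign-symmetric.

The full-pipeline order is resample → denoise → normalize → polarity.
Denoising after resampling puts the level-1 detail band at the same
frequencies (25–50 Hz) for every source device; denoising a 300 Hz
record natively would place the band at 75–150 Hz, leaving the 0–50 Hz
noise that survives downsampling untouched.  Normalizing after
denoising makes the rendered amplitude range exact.  The library
functions can be composed in any order when a different trade-off is
wanted.

## Segmentation and R-peak detection

Records are cut into contiguous, non-overlapping windows of
`round(seg_seconds * fs)` samples (10 s default); a 30 s record yields
exactly three.  The first window can be anchored at the first detected
R peak so every window starts on a beat; the trailing partial window is
dropped so each image represents a full window.  If anchoring would
leave no room for a single full window, the origin is used.

The detector is Pan–Tompkins in structure: band-pass 5–15 Hz
(zero-phase), differentiate, square, 150 ms moving-window integration,
then peak picking with a 200 ms refractory period.  The height floor is
adaptive to the envelope — `max(0.25 * peak, 2 * median)` — so small
inter-beat ripples are rejected at any overall scale and a flat signal
yields no peaks.  Candidate positions are refined to the strongest
absolute band-passed excursion within ±100 ms, which makes detection
polarity-independent.  On noiseless synthetic trains from 50–150 bpm
the detector holds ≥95% sensitivity and positive predictive value
against the generator's ground-truth beat times (50 ms tolerance).

## Rasterization

Each segment (already in `[-1, 1]`) becomes a 96×96 binary image: time
maps to columns through integer edges `(c*L)//96` so every sample
belongs to exactly one column; each column is drawn as the filled
min–max envelope of its samples, with +1 at the top row.  Row indices
are computed through a single floor-based helper applied
antisymmetrically, so `rasterize(-x)` is the exact vertical mirror of
`rasterize(x)` regardless of floating-point rounding at pixel
boundaries; the zero line, which falls on a pixel-grid boundary for
even heights, lights both middle rows.  There are no axes, margins or
anti-aliasing, and the output is byte-for-byte deterministic.  96×96
was chosen over higher resolutions to keep the classifier small; one
pixel column spans ~0.1 s of a 10 s segment.

## The 2-D classifier

Four blocks of convolution → ReLU → max-pool → dropout, then
flatten → dropout → dense(96, ReLU) → dense(1, sigmoid):

| layer | kernel | filters | pool | parameters |
|-------|--------|---------|------|-----------|
| conv1 | 3×3    | 32      | 2×2  | 320 |
| conv2 | 3×1    | 64      | 2×2  | 6,208 |
| conv3 | 3×1    | 128     | 2×2  | 24,704 |
| conv4 | 3×1    | 128     | 3×2  | 49,280 |
| dense | —      | 96      | —    | 295,008 |

The kernel and pooling schedule is pinned by the parameter counts: 320
forces 3×3×1 kernels in conv1, 6,208 forces 3×1 kernels from conv2 on,
and 295,008 = 96 × (3072 + 1) forces a 3,072-feature flatten, which the
(2,2)×3 + (3,2) pooling of a 96×96 input produces (4×6×128).  The five
counts sum to 375,520; the output layer adds 97.  Dropout rates are
0.25/0.25/0.4/0.5 per block plus 0.5 after the flatten.

Training uses binary cross-entropy (labels: norm = 1, afib = 0) with
Adam (lr 1e-3, batch 32), a 20% validation split, and early stopping on
validation loss (patience 5, best weights restored).  The loss is
binary cross-entropy rather than a multi-class softmax because the
output layer is a single sigmoid unit; dropout provides the
regularization.  Weights are initialized Glorot-uniform — with He
initialization the four max-pool stages compound an upward bias in the
activations and the initial loss starts far from ln 2, stalling
training.  The network is implemented directly on numpy arrays
(float32; shift-and-matmul convolutions, argmax-routed pooling,
inverted dropout), with every random draw taken from one seeded
generator, so a fixed seed reproduces a training run exactly on a fixed
BLAS.  Dropout is disabled at inference, so prediction is
deterministic.

Odd input sizes are pooled by floor division (a 95×95 input yields a
3×5×128 = 1,920-feature flatten); construction fails only if a spatial
dimension vanishes.

## Decision layer

Per segment, the label is norm iff the sigmoid score clears the
decision boundary, and the confidence is the score for a norm call and
its complement for an afib call — both classes then live on the same
[0, 1] scale.  The record label maximizes the summed confidence per
class, for any segment count; ties go to afib (favouring sensitivity in
screening).  For ROC analysis and boundary sweeps the per-record score
is the mean raw sigmoid score across segments.  The boundary sweep
maximizes accuracy over a grid, breaking ties toward the value closest
to 0.5 (extreme cutoffs generalize poorly) and then toward the smaller
value.

## Metrics

AFib is the positive class.  Sensitivity `TP/(TP+FN)` and specificity
`TN/(TN+FP)` return NaN — not zero — when undefined.  AUROC accumulates
the trapezoidal rule over distinct score thresholds, which equals the
Mann–Whitney pairwise-ordering probability with half credit for ties
(verified against a brute-force pairwise oracle to 1e-12, and against
scikit-learn's implementation in tests).

## Synthetic data: what it emulates, and what it does not

Each beat is a sum of Gaussian bumps (P, Q, R, S, T) with fixed offsets
and widths; the generator therefore knows every true beat instant.
Normal rhythm draws RR intervals with 2% jitter; AFib draws them
log-normally with coefficient of variation ≈ 0.25, removes the P wave,
and adds four incoherent 4–9 Hz tones of 0.03–0.05 mV each —
0.12–0.20 mV of fibrillatory baseline in total, the published
coarse-AF f-wave range, and deliberately below the 25 Hz denoising
boundary so preprocessing cannot erase the class signal.  Biphasic
polarity subtracts a delayed (24 ms), 1.25× copy of the R bump,
mimicking V1–V3 morphology.

Device profiles fix the study conditions: `clinical_100` / 
`clinical_500` are 10 s upright lead-I records at 100/500 Hz with
amplitude scale 0.8–1.2; `smart_300` is 30 s single-lead at 300 Hz with
amplitude scale 0.4–1.6 and a 25% chance of inverted polarity
(electrode reversal).  All records carry baseline wander (0.03–0.10 mV,
0.2–0.5 Hz), broadband noise (0.01–0.04 mV) and powerline interference
(0.01–0.03 mV, 50 Hz) — magnitudes typical of recordings that have
passed a device's acquisition filters.  Everything derives from one
seed per record.

The generator does *not* emulate: muscle-artifact bursts, electrode
pop, pathologies other than AFib, respiratory modulation, QT/heart-rate
coupling, or a 12-lead vector projection.  Passing the end-to-end test
therefore shows that the pipeline machinery — harmonization, rendering,
training, voting — preserves and exploits the canonical AFib surface
features across a simulated device gap; it does not certify clinical
performance on real recordings.

## The cross-device experiment

`run_crossdevice_experiment` trains on 200 records/class of
`clinical_100` (one image each), picks the decision boundary by an
accuracy sweep on an independent 25/class `smart_300` calibration set
(per-model cutoff selection without touching the test set), and
evaluates on 50/class `smart_300` records through the full
harmonize-segment-vote path.  30 epochs suffice for the validation
accuracy to plateau (~0.95–0.98); at seed 7 the held-out accuracy is
0.92 with AUROC 0.986.  The residual errors are low-amplitude
(≤0.6 mV), high-noise normal records whose relative noise after peak
normalization renders like fine fibrillation — the genuinely ambiguous
cross-device cases.  The run takes roughly five minutes on one CPU;
problem sizes were chosen so the whole experiment, including data
generation and preprocessing, stays at desk scale.

## Known limitations

* The WFDB reader handles format 16 only; no annotation files.
* The R-peak detector's fraction-of-maximum floor assumes reasonably
  stationary QRS amplitude within a record; amplitude-modulated or
  burst-noise records would need the full adaptive SPKI/NPKI tracking.
* The CNN is intentionally small and its 3×1 kernels look mostly along
  the amplitude axis; horizontal (rhythm-spacing) structure is captured
  only through the deep receptive field.
* Thresholded wavelet denoising removes only detail-band energy; wander
  below fs/4 is left to the polarity high-pass and is still present in
  the rendered images.
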