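# Methods

This note records the models implemented in `emgfall`, the assumptions and
parameter choices behind them, and what the synthetic benchmark does and
does not demonstrate.

## Signal model and preprocessing

sEMG is treated as a band-limited stochastic interference signal: useful
power lies in roughly 10–500 Hz, below which motion artifact and baseline
drift dominate and above which there is only noise. Denoising is a cascade
of a 3rd-order Butterworth high-pass at 10 Hz and a 3rd-order Butterworth
low-pass at 500 Hz. Discretisation uses the bilinear transform with
frequency pre-warping, so each stage passes exactly −3.01 dB at its printed
cutoff; a 3rd-order Butterworth stage rolls off at 18 dB/octave
(`|H(f)|² = (f/f_c)⁶ / (1 + (f/f_c)⁶)` for the high-pass). No power-line
notch is applied — the emulated acquisition hardware shields interference
and a 50 Hz notch would cut into the signal band.

Application is **causal single-pass by default** (preserving the real-time
framing of an alarm system); zero-phase forward–backward filtering is
available via `zero_phase=True` but squares the magnitude response, so
roll-off figures quoted above refer to the single pass. Edge transients are
not padded away; analyses that care discard the first 0.2 s.

## Active-segment extraction

Detection statistic: mean short-term energy of disjoint n-point windows
(n = 100 at 1500 Hz; the hop is exposed but defaults to n). Multichannel
recordings are reduced to one decision signal by the root-sum-of-squares
across channels, making the combined energy the sum of per-channel
energies; a single decision rule avoids per-channel conflict resolution.

Thresholds are **static and calibrated**: over manually segmented
intervals, the mean ratio of boundary energy to interval peak energy,
multiplied by the peak energy of the remaining ("rest") data, gives the
onset threshold STS and offset threshold STE. The onset rule additionally
requires a rising edge (mean of the previous `l` energies below the
current) and sustained activity (mean of the next `m` energies above STS);
the offset rule requires a decaying tail (mean of the next `l` energies
below the current). At the canonical operating point `l = fs/(2n) = 7.5`
is not an integer; it is rounded half-to-even to 8, and `m` is the rounded
midpoint (11) of the admissible open interval (7.5, 15). Both are
configurable. The prose of the onset look-ahead is ambiguous between
"the mean of the next m windows exceeds STS" and "each of them exceeds
STS"; the mean reading is the default and the per-window variant is
selectable (`lookahead_mode="per_window"`).

Detections shorter than 0.3 s are discarded: they cannot fill even one
200 ms analysis window with a 100 ms step. An onset can only be declared
from window `l` onwards (a full look-back must exist), so recordings are
expected to begin with a rest lead-in — true of the emulated protocol,
where subjects rest between repetitions.

In cross-validated evaluation the calibration uses 20% of each *training*
subject's recordings (generator annotations standing in for manual marks)
and the rest of the training data for the peak; the held-out subject is
segmented with those frozen thresholds. This is the leakage-free choice;
calibrating on the test subject's own data would be the more favourable
but contaminated alternative.

## Features

**Spectrograms (SPM).** Segments are framed into 300-sample windows with a
150-sample step; a frame count of `floor((len − 300)/150) + 1`. Each frame
is weighted by the Hamming taper `W(n) = (1−a) − a·cos(2πn/(N−1))` with
a = 0.46 — the first side lobe of this taper sits ≥ 40 dB below the main
lobe (the package measures ≈ 44.6 dB on a 16× zero-padded spectrum), which
is what keeps spectral leakage from smearing the band-limited class
signatures. The FFT length is the next power of two (512), magnitude (not
power) spectra are kept, bins outside 10–500 Hz are dropped (167 bins
remain), and each segment-channel image is min–max normalised to [0, 1] —
channel gains are arbitrary, so only relative spectral shape is retained.
A log-magnitude variant is available behind a flag.

**PCA.** The frequency axis is reduced to k = 8 orthonormal components
fitted on pooled training-fold frames (all channels together). The
explained-variance table is emitted per fit; its values depend on the data
and are reported, not asserted. PCA is always fitted per cross-validation
fold and applied to that fold's test data.

**Time-domain features.** Per window and channel: MAV, population VAR, WL,
RMS, ZC and SSC (the slope-sign-change indicator averaged over the n−2
interior points). The zero-crossing dead-band ε defaults to 0.01 × window
RMS, keeping the count amplitude-scale invariant. All six match naive loop
oracles to 1e−10 relative tolerance in the test suite.

## Classifier

The dual-parallel-channel CNN consumes tiles of shape (8 time frames, 8
PCA components, 4 muscle channels); the muscles enter as input depth so
convolutions mix channels and capture co-contraction. Branch 1 uses 2×4
kernels (rows = time, columns = components), branch 2 the transposed 4×2;
filter counts are [10, 20, 20] with 2×2/stride-2 max pooling after the
first two convolutions, "same" zero padding (an 8×8 input would be
annihilated by valid padding), ReLU activations, and a shared dense head
[40, 10, 4] with dropout 0.5 between dense layers and a softmax output.
The printed kernel triples (e.g. "2 × 4 × 1") are read as height × width ×
incoming depth, the depth being dictated by the previous layer rather than
free. Ablations: DPC1 duplicates branch 1, DPC2 duplicates branch 2
(identical parameter counts by kernel transposition), and the
single-channel CNN uses one branch of square 2×2 kernels.

Segments longer than 8 frames contribute several tiles (stride 4 frames,
final tile right-aligned); shorter segments are edge-padded. Segment-level
predictions average the window-level probability vectors — the simplest
pooling consistent with window-level training.

The engine is written in numpy with explicit backprop (float64;
gradient-checked against central differences to 1e−4). Training uses
minibatch Adam (learning rate 1e−3, batch 32, ≤ 100 epochs with optional
early stopping on held-out loss), categorical cross-entropy as the loss
pairing of the softmax output, and is bit-deterministic under a seed.
Classical baselines (RBF-kernel SVM, LDA, 5-NN) wrap scikit-learn
estimators on per-segment summary vectors (mean and standard deviation of
the reduced-spectrogram frames, or of the time-domain feature table) after
per-fold standardisation.

The "RMS" feature mode for the CNNs arranges per-window RMS values as an
(8 frames × 4 channels × 1) image, min–max normalised per segment — the
input layout is otherwise unspecified for scalar features.

## Evaluation protocol

Folds are leave-one-subject-out: all recordings of one subject form the
test set, preventing identity leakage. Everything data-dependent
(segmentation thresholds, PCA, feature standardisation, model weights) is
recomputed per fold from training subjects; each fold's report carries a
fingerprint of its training recordings for audit. Metrics are accuracy,
sensitivity and specificity in percent on the binary fall-vs-daily
collapse (training remains 4-class), pooled over each fold's segments,
with per-fold values and means reported. A metric with a zero denominator
is reported as missing with a diagnostic, never as 0. Recordings in which
no segment is detected contribute no samples to their fold; on the easy
setting recovery is ≥ 90%, so this is rare. Wall-clock rows in the report
are informational only.

## Synthetic data: what it emulates, and what it does not

The generator emulates the structure the pipeline assumes: cohorts of
subjects (default 10 × 4 gestures × 10 repetitions = 400 recordings, 100
falls), 4 channels at 1500 Hz, 3–5 s recordings containing one activity
burst in zero-mean Gaussian baseline noise. Bursts are band-pass-filtered
Gaussian noise under a trapezoidal activation envelope — the stochastic
interference-pattern character of sEMG without motor-unit modelling. Class
identity is carried by the carrier band (walking 25–130 Hz, squatting
70–190 Hz, sitting 150–290 Hz, falling 200–470 Hz — falls broad-band and
high-frequency) and a per-class 4-channel loading pattern; falls
co-contract all channels at slightly higher amplitude (×1.1). Envelope
timing: 0.06 s rise (fast activation), 0.9–1.6 s plateau, 0.30 s fall
(slower relaxation), with ≥ 0.9 s rest before the burst — the rest between
repetitions in the emulated protocol, and enough history for the onset
rule's look-back. Combined-channel burst energy is kept comparable across
classes (channel patterns normalised to unit RMS, mild lognormal gain
jitter), because a single pair of static thresholds must serve a whole
cohort and gross amplitude is a poor discriminator on real electrodes.

Ground-truth intervals follow a manual-marking convention: the start is
annotated at the foot of the sharp activation rise, the end at the
half-maximum of the gradual relaxation ramp. This keeps both calibrated
thresholds inside monotone energy-ramp regions, where the onset/offset
rules trigger deterministically rather than on noise coin-flips.

Difficulty is a single knob: burst-to-noise RMS per channel (easy = 6,
hard = 1.5). Class separability grows monotonically with burst amplitude
(tested via the distance between class mean spectra). Optional 50 Hz mains
injection (default off) exists for filter tests.

**Not emulated:** motor-unit recruitment and firing statistics, fatigue,
electrode lift/shift artifacts, cross-talk between muscles, inter-session
electrode placement variability, and realistic inter-subject spectral
differences (subjects differ only in gains and noise draws). Passing the
synthetic benchmark therefore demonstrates that the pipeline's machinery
is correct and leakage-free and that it can exploit band/channel
signatures — not that the reported accuracies transfer to clinical
recordings. The easy-setting accuracies (often 100% at desk scale) are a
property of the cleanly separable synthetic classes.

## Numerical and degenerate-input choices

- Filters: second-order-sections throughout; stability asserted at design
  time (all poles inside the unit circle). Zero magnitude is reported as
  −inf dB.
- All-zero segments produce all-zero spectrograms flagged `degenerate`
  (normalisation skipped) and all-zero feature tensors.
- Max-pool gradient splits equally among tied maxima; with continuous
  activations ties are vanishingly rare.
- Softmax shifts by the row maximum before exponentiation.
- `l` rounding is half-to-even; `m` is nudged inside its open interval if
  rounding lands on a boundary.
- Segments are half-open `[start, end)` in samples, 0-based.

## Scale of the shipped experiments

Tests and examples run the pipeline at desk scale — typically 4–5 subjects
× 4 gestures × 5 repetitions (80–100 recordings) with ≤ 50 training
epochs — the package's chosen balance between statistical meaningfulness
and quick iteration; the generator's defaults remain the full 400-recording
cohort. All experiment entry points accept the full scale unchanged.

## Known limitations

- Static thresholds assume cohort-comparable signal energy; strongly
  heterogeneous gains (or the hard noise setting) degrade segmentation, by
  design of the method.
- The numpy network engine is single-threaded and eager; it is sized for
  the 8×8×4 tiles of this pipeline, not for large images.
- The SVM baseline's probability calibration (scikit-learn's internal
  cross-validation) is the only non-essential stochastic element in the
  baselines; predictions used for metrics come from `predict`, which is
  deterministic under the recorded seed.
- Streaming/online segmentation and adaptive thresholds are out of scope.
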