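# Methods

## Problem

Intravascular ultrasound (IVUS) pullbacks image a coronary artery at a fixed
frame rate (30 fps by default) while the catheter is withdrawn at constant
speed. The heart keeps beating during the pullback, so consecutive frames
mix cardiac phases; serial or volumetric measurements need *gating* — the
selection of one frame per cardiac cycle at the same phase. The natural
phase is end-diastole: the instant of the ECG R-peak, when lumen motion
relative to the catheter is minimal. When no ECG channel was recorded, the
end-diastolic frames must be recovered retrospectively from the images
alone. This package implements such a retrospective detector, a
conventional image-based comparator, the full evaluation machinery, and a
synthetic pullback generator that provides ground truth at desk scale.

## Motion signal

Each frame is median-filtered (3×3 by default) to suppress speckle
outliers. The absolute grayscale difference between corresponding pixels of
consecutive frames is summed over the whole image, giving one scalar per
frame that tracks lumen motion relative to the probe. The series is smoothed
with a Hanning window normalized to unit sum (13 frames by default at
30 fps) using reflect padding, and min–max scaled to [0, 1] per sequence
before it reaches the detector.

Indexing convention: `values[i]` describes the motion *into* frame `i`, with
`values[0] = 0`, so the signal has exactly one entry per frame and a
sequence of `n` frames yields `n − 63` sliding windows of length 64.

## Detector

A bidirectional gated recurrent unit (Bi-GRU) network scores 64-frame
windows of the prepared signal: the forward and backward passes each produce
a final hidden state (64 units per direction by default); the concatenated
states feed a dense layer with a logistic output, interpreted as the
probability that the window's anchor frame (0-based offset 31, i.e. the
32nd frame) is end-diastolic. The 64-frame span holds at least two cardiac
cycles for cycle lengths of 19–30 frames — one full cycle is necessary to
identify the phase, and the surplus context helps localize it.

Training minimizes the mean square error between the predicted anchor
probability and a soft target: the end-diastolic indicator blurred with a
Gaussian of SD 2 frames. A hard 0/1 target would put one positive among
~25 windows and make the MSE gradient extremely sparse; the soft label
keeps the loss informative while preserving a sharp maximum at the true
frame. Optimization uses Adam at learning rate 1e-3, up to 50 epochs at
batch size 1 by default, with no validation split or early stopping; all
initialization and shuffling derive from a single seed, so training is
exactly reproducible. The GRU forward pass, backpropagation through time
and Adam are implemented directly in numpy, vectorized over the batch, and
verified against finite-difference gradients in the test suite.

At inference a window slides over the whole sequence and every frame
receives the probability of the window anchored on it; the first 31 and
last 32 frames have no natural window, so the signal is reflect-padded
(disable with `pad_edges=False` to score edge frames as zero). Detections
are the local probability maxima above a threshold (0.3), accepted greedily
in descending probability with a minimum spacing of 13 frames — matching
the smoothing window and safely below the shortest plausible cycle at
30 fps. Models are trained separately per vessel type (LAD, LCx, RCA),
since the three arteries show different motion amplitude patterns.

## Conventional image-based baseline

The comparator is a deterministic, training-free gater over the same
smoothed signal: the dominant cycle length `P` is estimated from the
autocorrelation peak in a 15–45 frame band, then local minima are accepted
greedily in ascending signal value subject to a minimum spacing of 0.6·P;
remaining gaps wider than 1.6·P are closed with the lowest-valued frame
that keeps the spacing valid. Minima are targeted because end-diastole is
the quiescent phase. No randomness is consumed: repeated runs are
bit-identical. The output is tagged `cib-standin`; it reproduces the
*structure* of a conventional image-based comparison, not any particular
commercial implementation.

## Evaluation

Detections are compared with R-peak-aligned references using the
matched / extra / missed convention: each estimate is assigned to its
nearest reference (ties to the earlier reference); per reference, the
closest assigned estimate (ties to the earlier estimate) is the matched
pair; surplus assigned estimates are extra and unclaimed references are
missed. By construction |matched| + |missed| = |references| and
|matched| + |extra| = |estimates|.

Signed differences (estimate − reference) in milliseconds feed:

* **Fixed accuracy** — a pair is correct when |diff| ≤ 100 ms. The boundary
  is inclusive (with 1e-9 slack) because 3 frames at 30 fps is exactly
  100 ms and the tolerance is three times the temporal resolution.
* **Relative accuracy** — |diff| ≤ 10% of the local R-R interval (the gap
  to the next reference; the last reference reuses the preceding gap).
* **Bland–Altman** — mean difference, sample SD (n−1), limits of agreement
  at mean ± 1.96·SD.
* **RMSE** and Pearson chi-square (no continuity correction) for count
  tables.

Accuracy uses either the matched count or all estimates
(matched + extra) as denominator; both conventions are exposed. Aggregation
over vessels sums counts before percentages are computed.

## Synthetic pullbacks

The generator renders a cross-sectional lumen (dark interior, bright wall
ring, optional slow texture drift emulating the pullback) whose center and
radius follow a cardiac waveform, with multiplicative Rayleigh-like speckle
applied last. Design choices that matter:

* **Cycle machinery.** End-diastolic frames start at frame 0 and advance by
  cycle lengths drawn around `fps·60/hr_mean` with fractional SD
  `hr_jitter` (default 0.05, typical resting sinus variability). 60–94 bpm
  at 30 fps gives the 19–30-frame cycles of clinical sequences.
* **Fixed-duration active phase.** Systolic contraction plus rapid filling
  lasts 0.55 s regardless of heart rate; rate changes stretch only the
  diastasis plateau that ends at the next end-diastolic frame. This mirrors
  cardiac physiology (systole shortens only mildly with rate) and makes the
  motion-burst shape rate-invariant, so a detector trained at one heart
  rate transfers to another.
* **Closed-loop motion.** The lumen center traces a small closed loop per
  cycle with a half-sine speed profile (brisk takeoff right after the
  R-peak) instead of retracing a line. A back-and-forth path would produce
  two dissimilarity bursts per cycle (out-stroke and return), a morphology
  whose shape encodes the rate; the loop gives the single
  quiescence-then-burst pattern seen in real dissimilarity signals.
* **Vessel types.** Cohorts contain equal numbers of LAD, LCx and RCA
  vessels with motion-amplitude multipliers 1.0 / 1.2 / 1.6. The relative
  ordering (RCA most mobile) is physiologic but the specific values are
  invented — no quantitative amplitudes are available — and per-vessel
  heart rates are drawn uniformly within ±15% of the cohort mean.
* **R-peak convention.** The R-peak coincides exactly with the
  end-diastolic frame; phase is zero there and the noise-free motion
  waveform has a local minimum.

What the generator does **not** emulate: real speckle decorrelation
statistics, catheter ring-down and guidewire artifacts, breathing motion,
arrhythmia (sinus rhythm only), NIRS content, or vessel curvature. Passing
tests therefore demonstrate that the pipeline recovers end-diastole under
the motion model the method assumes — not clinical performance.

## Frame-rate study

The 15 fps arm keeps frames at even 0-based indices and maps reference
indices with floor(i/2) (duplicates collapse with a warning); correctness
still uses the fixed ±100 ms cut-off, which is ±1 frame at 15 fps.
Frame-count parameters defined at 30 fps are rescaled by fps/30 (peak
spacing 13 → 6, period band 15–45 → 8–22). Two parameters follow their own
rules, both documented design choices:

* the smoothing window drops to 3 frames below 20 fps — the diastasis
  trough spans only 2–4 frames at half rate and a ~450 ms window would
  erase it, while the doubled per-frame motion increment improves the
  signal-to-speckle ratio enough that little smoothing is needed;
* the detector window halves to 32 frames (anchor 15) so its *physical*
  span — two-plus cardiac cycles — is preserved. Keeping 64 frames at
  15 fps would span five or six cycles and reward brittle
  period-extrapolation over the local quiescence cue.

## Problem sizes and defaults used in the shipped experiments

The acceptance script and the heavy tests simulate two vessels per type at
3000 frames, 30 fps, 128-px frames, mean heart rate 75 bpm (per-vessel
draws span ~64–86 bpm), speckle scale 0.2 and drift 0.05 px/frame, and
train with 32 hidden units per direction, 20 epochs at batch size 16 — a
compact training schedule for the desk-size cohort; the full-scale
settings (64 units, 50 epochs, batch 1) remain the `DetectorConfig`
defaults. Leave-one-out cross-validation is per vessel type, fold seeds
derive deterministically from the configured seed, and every pipeline is
bit-reproducible from that single seed.

## Known limitations

* With two vessels per type, each cross-validation fold trains on a single
  vessel; accuracy is accordingly sensitive to how representative that
  vessel's heart-rate range is.
* The conventional-gating comparator stands in for the published
  commercial algorithm, whose exact procedure is not public; only its
  qualitative properties (deterministic, periodicity-constrained,
  training-free) are reproduced.
* Stented or heavily calcified segments, non-sinus rhythm and frames with
  imaging artifacts are out of scope.
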