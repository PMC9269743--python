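# Methods

`glucosynth` synthesizes per-patient single-day continuous glucose
monitoring (CGM) profiles with a 1-D convolutional generative adversarial
network (GAN), certifies the synthetic cohort statistically against the
real one, and uses accepted synthetic days to augment the training set of
a nocturnal-hypoglycemia classifier.  This note documents the models, the
defaults and their rationale, the numerical choices, and what the fixture
patients do and do not establish.

## Day representation and preprocessing

A CGM trace is a timestamped glucose sequence (mg/dL) at a nominal
5-minute cadence.  Traces are regularized onto a strict 5-minute grid:
readings within ±90 s of a slot are snapped to it (commercial CGM exports
drift by a few seconds per reading); larger offsets are treated as
unreliable and the slot left missing.  Values are clamped to
[40, 400] mg/dL, the reporting range of common CGM hardware, which gives
every model a fixed support.

Missing runs strictly shorter than one hour (i.e. at most 11 consecutive
5-minute slots) are filled by linear interpolation between the flanking
readings; such dropouts are punctual signal losses and the interpolation
error is small relative to sensor noise.  Longer outages (battery,
sensor replacement) are left missing, and any 24-hour window still
containing a missing value is dropped whole rather than split or
zero-filled — the models consume only complete, fixed-width rows of 288
values.  The window anchor is configurable: midnight for generative
modelling; 17:00 when building classifier data, so a single row spans
both the pre-sleep feature window (17:00–22:00) and the night to be
labeled (22:00–06:00).

## Glycemic outcome metrics

The standard consensus bands are used, half-open at every boundary:
level-2 hypoglycemia [40, 54), level-1 hypoglycemia [54, 70), time in
range [70, 180), hyperglycemia [180, 400].  Percentages are over all
samples of a day-set and sum to 100 by construction.  Summary moments use
the population convention (ddof = 0) so `sd**2 == variance` exactly.

## Generator and discriminator

The generator maps a 100-dimensional standard-normal latent vector
through a dense layer into 50 parallel low-resolution sequences of length
72, then alternates nearest-neighbour upsampling and convolution
(two ×2 stages, kernel 9, channels 32 then 16; 72 × 2 × 2 = 288), and
finishes with a single-channel kernel-9 convolution under tanh.  The tanh
output is mapped affinely from [−1, 1] onto [40, 400] mg/dL, mirroring
the normalization applied to real days.  The discriminator is the mirror
image: three strided convolutions (kernel 9, stride 2, channels
16/32/64) with leaky-ReLU (slope 0.2), flattened into a single sigmoid
unit emitting P(real).  The latent width follows the deep-convolutional
GAN convention; the channel widths were chosen as the smallest that
reliably reproduce the per-day outcome distributions of the fixture
patients at single-CPU scale.

Layers, backpropagation and the Adam optimizer are implemented in numpy
(`glucosynth._nn`): convolutions are im2col + BLAS matmul, single
precision inside the networks (double precision everywhere else).  All
randomness — initialization, shuffling, latent draws — derives from one
integer seed, so training and generation are bit-reproducible.

## Adversarial training and model selection

Training is the standard minimax game with binary cross-entropy and 1:1
alternating updates: the discriminator is fit to label real days 1
(smoothed to 0.9 — one-sided label smoothing noticeably stabilizes the
game at this data scale) and generated days 0; the generator is updated
through the frozen discriminator toward the real label.  Adam uses
learning rate 2×10⁻⁴ and first-moment decay 0.5 for both networks; batch
size 16 (the gradient noise of small batches helps the generator cover
the rare hypoglycemic-day mode); up to 1500 epochs.  One GAN is trained
per patient, never pooled: the point is to replicate an individual's
glycemic distribution.

Adversarial training does not converge monotonically — epochs that match
the real per-day outcome distributions alternate with epochs that drift —
so the statistical certification below doubles as the model-selection
criterion: every 25 epochs the battery is evaluated on the training days
(worst case over three generation/subsampling draws), the
best-scoring snapshot (largest minimum p-value) is retained, and training
stops early once that score clears a comfortable margin (0.25).  The
returned model is the selected snapshot.  This uses training data only;
no held-out information is consumed.

## Statistical certification of a synthetic day-set

For each of five per-day metrics — the four band fractions and the day
mean — a Wilcoxon rank-sum test compares the real days with an
equal-sized seeded subsample of synthetic days (synthetic cohorts are
generated with at least as many days as the real set).  The unpaired
rank-sum variant is the default because real and synthetic days have no
natural pairing; a signed-rank mode (pairing by order statistics) is
available behind a flag.  The cohort is accepted iff every p ≥ 0.05:
a high p-value means no detectable distributional difference.  With ~90
days per group the test is sensitive to shifts of a few mg/dL in the day
mean, so acceptance is demanding; p-values for the rare hypoglycemia
bands sit on a discrete lattice (many tied zeros) and can land near the
threshold for borderline models.

The report also carries:

* **Jensen–Shannon distance** between pooled glucose histograms,
  JSd = √((D(P‖M) + D(Q‖M))/2), M = (P+Q)/2, logarithms base 2 so the
  value lies in [0, 1].  Histograms use fixed shared edges over
  [40, 400] at 10 mg/dL width — fixed edges make every pairwise
  comparison well-defined.  Zero-mass bins contribute nothing to their
  own KL sum; the mixture is positive wherever either input is.
* **Per-day JS heatmaps** (each day against each day): the real–real map
  has a zero diagonal; a trained generator's real–synthetic map must
  contain no zeros — the generator must not copy training days.  This is
  complemented by a circular-shift check: no synthetic day equals any
  rotation of a real day (correlation < 1 − 10⁻⁶ after normalization).
* **Z statistic** on per-day means, |m̄_r − m̄_s|/√(s_r²/n_r + s_s²/n_s).

## Night classification and augmentation protocol

A night is positive when the monitor registers at least three consecutive
readings strictly below 70 mg/dL between 22:00 and 06:00 (96 samples);
a reading of exactly 70 breaks a run.  Features are exclusively the 60
readings from 17:00 to 22:00 — information after 22:00 is used only for
labeling.  Synthetic nights are labeled by the same rule applied to
generated rows; no other labeling rule is consistent with the event
definition.

The classifier is a small 1-D conv net of the discriminator family scaled
to the 60-sample input: two convolution blocks (kernel 5, channels 8/16,
leaky-ReLU 0.2, max-pool 2), dense to one sigmoid unit, threshold 0.5,
Adam at 3×10⁻³ for 25 epochs.  Class weights are not used: augmentation
itself is the imbalance remedy under study.

Evaluation is repeated stratified 5-fold cross-validation over the real
instances; 5 is the smallest k that keeps at least one minority instance
per fold for eligible patients.  Patients with fewer than five positive
nights are ineligible (an explicit exclusion result, not a silent skip).
Synthetic instances are appended to training folds only; test folds are
structurally real-only.  Repetition r uses seed base+r for the fold
shuffle and classifier initialization.  Per-fold metrics — accuracy,
sensitivity (positive-night recall), specificity, Gmean = √(SEN·SP), and
the Matthews correlation coefficient — are aggregated as medians over
fold × repetition.  The size sweep repeats the protocol for a grid of
synthetic-set sizes and summarizes how the Gmean gain from the first to
the middle size compares with the gain from the middle to the last.

## The fixture patients

Real CGM cohorts in this problem area sit behind data-use agreements, so
the package ships a statistical fixture generator instead: basal level +
circadian sinusoid (minimum ~03:00) + jittered meal excursions
(30-minute linear rise, exponential decay) + a per-day level offset +
AR(1) noise (φ = 0.9, stationary SD = `noise_sd`), clamped to [40, 400].
Nights selected with probability `hypo_night_prob` receive a broad
negative excursion from the late evening onward plus a sharp dip that
guarantees the three-consecutive-sub-70 event; the evening portion makes
pre-sleep glucose genuinely predictive of the label, as in real
patients.  Two presets bracket moderately and poorly controlled adults
(per-day outcome ranges ≈ hyperglycemia 20–60 %, TIR 40–70 %, L1
0.5–7 %, L2 0–12 %, mean 130–200 mg/dL, positive-night prevalence
3–30 %).

What the fixture does **not** emulate: insulin/meal/exercise dynamics,
sensor artifacts (compression lows, calibration jumps), day-of-week
structure, and long-range autocorrelation beyond AR(1).  Passing the
acceptance battery on fixtures therefore demonstrates that the method
reproduces per-day outcome distributions it was pointed at — not
clinical realism of the waveforms, and not performance on real cohorts.

## Problem sizes and defaults

The shipped experiments use one simulated patient with 91 days (~90
complete nights, ~15 % positive), GAN training capped at 1500 epochs with
certification checks every 25, a 1000-instance augmented condition with
20 repetitions, and a sweep over {500, 1500, 3000} synthetic instances
with 5 repetitions.  These sizes keep a full pipeline run in the
tens-of-minutes range on one CPU core while leaving every comparison
adequately powered; all of them are parameters, not constants.

## Known limitations

* Adversarial training at ~90 training days is noisy; a minority of
  seeds select snapshots for which a fresh certification draw lands
  marginally below the 0.05 threshold on one band metric.  The
  worst-case-over-draws selection score reduces but does not eliminate
  this.
* The certification battery tests per-day marginals, not temporal
  structure within the day beyond what the discriminator enforces.
* The night classifier is deliberately small and uses glucose only; it
  is a vehicle for measuring the augmentation effect, not a clinical
  predictor.
* Generated days are unconditional: no insulin, meal, or activity
  conditioning.
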