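# Methods

`ecgbeat` classifies single ECG beats into eight classes — normal (N), left
and right bundle branch block (LBBB, RBBB), atrial premature contraction
(APC), nodal escape (NESC), aberrated atrial premature (ABERR), nodal
premature (NPC) and atrial escape (AESC) — from heavily imbalanced data.
The design target is the MIT-BIH arrhythmia database (48 two-channel
records at 360 Hz with expert beat annotations), where the normal class is
roughly 80% of the 93,371 eight-class beats and the rarest class has 16.
Rather than resampling the data, imbalance is addressed in the objective:
the network trains on focal loss, which downweights confidently classified
(easy, overwhelmingly normal) beats.

## Preprocessing

**Denoising.** Each record's channel-0 signal passes through a multilevel
Daubechies-6 (db6) discrete wavelet decomposition with symmetric extension.
Two modifications are applied before reconstruction:

* the deepest approximation band is zeroed to remove baseline wander —
  but only when that band lies at or below 1 Hz.  At 360 Hz the requested
  depth of 9 gives a 0–0.35 Hz approximation band, squarely the
  baseline-drift range.  On short segments the achievable depth is capped
  by signal length (a 250-sample beat supports at most level 4, whose
  approximation band spans 0–11 Hz and contains the beat itself), so the
  guard keeps the approximation there and denoising reduces to detail
  thresholding.  This makes the same function safe on whole records and on
  already-segmented beats.
* detail levels 1–2 (above ~45 Hz) are soft-thresholded with the universal
  threshold `σ·sqrt(2 ln N)`, with `σ = median(|d₁|)/0.6745` estimated from
  the finest band.  A fixed threshold can be supplied instead; disabling
  both modifications gives perfect reconstruction (used as a self-test).

Because the decimated DWT only commutes with shifts that are multiples of
`2^level`, the denoiser's shift-equivariance property is verified at such
shifts, away from the boundary-affected region, with a fixed threshold
(the data-dependent σ estimate is the other source of shift sensitivity).

**Segmentation.** Beats are fixed 250-sample windows (≈0.7 s at 360 Hz)
with the annotated R-peak at within-beat index 125 — 125 samples before,
124 after; "centered" with an even window length forces this one-sample
asymmetry, fixed once as a convention.  Windows crossing a record boundary
are skipped and counted.  R-peak detection is out of scope: annotation
positions are taken as given.

**Normalization.** Each beat is independently z-scored with its sample
standard deviation, making beats amplitude-invariant and self-contained.  A
near-constant beat (std < 1e-12) becomes the zero sequence.

**Splitting.** The pooled beats are split beat-wise 10% test, then 10% of
the remainder validation, stratified per class with largest-remainder
rounding; every class keeps at least one member in the training set.
Patient-wise holdout is deliberately not the default: the reference
protocol pools all beats before splitting, and the synthetic generator has
no patient structure.  Splits are deterministic given the seed.

## Model

Each beat is fed one sample per timestep to a single LSTM layer; the final
hidden vector is the beat representation, followed by a ReLU
fully-connected layer (width 32 by default) and a linear output layer with
softmax over the classes.

Two cell variants are implemented with exact gradients:

* **standard** (default): gates act on `[a_{t-1}, x_t]`;
* **peephole-printed** (`standard_lstm=False`): all four gate
  pre-activations additionally receive the *previous* cell state
  `c_{t-1}` — including the output gate, which classic peephole cells feed
  with `c_t`.

The printed form follows the source description of the cell to the letter
(reading its self-referential `c_t = f_t·c_t + i_t·c_in` as
`f_t⊙c_{t-1}`, the only non-degenerate reading).  It is not the default
because (a) the reference implementation ran on TensorFlow 1.12, whose
LSTM layers do not feed cell state into the gates, so the printed bracket
is almost certainly a typesetting artifact; and (b) empirically the
unbounded cell state entering the sigmoid gates makes the variant
dramatically slower to train — under the desk-scale conditions below it
stays collapsed on the majority class while the standard cell reaches ~99%
accuracy.  Both variants pass the same finite-difference gradient checks.

**Initialization.** Glorot-uniform weights, zero biases except the forget
gate bias at 1 (keeps the cell state initially persistent).  All
randomness flows from one seeded generator; training is deterministic
given the seed on a single thread.

**Loss.** With `p` the predicted probability of the true class
(clamped at 1e-12 before the log):

    CE(p) = −log p            FL(p) = −(1−p)^γ · log p,  γ ≥ 0

`γ=0` recovers cross-entropy exactly; the default focusing parameter is
γ=2.  There is no class-balance α term, and batch aggregation is the
unweighted mean.  Gradients are exact backpropagation through time across
all 250 steps, including the cell-state pathways of the peephole variant
and the `(1−p)^γ` factor; no gradient clipping is applied (divergence
aborts with a diagnostic instead).

**Optimizer.** Nadam — Adam's bias-corrected moments with a
Nesterov-style lookahead on the first moment:

    m ← β₁m + (1−β₁)g        v ← β₂v + (1−β₂)g²
    θ ← θ − lr · (β₁·m̂ + (1−β₁)g/(1−β₁ᵗ)) / (√v̂ + ε)

with lr=0.002, β₁=0.9, β₂=0.999, ε=1e-8 (the usual defaults; the reference
work names the optimizer but not its settings).  At t=1 the step is
−sign(g)·lr·(1+β₁) per coordinate, up to ε.

**Reference defaults** mirror the source configuration: 64 LSTM cells,
dropout 0 (applied, when nonzero, to the final hidden vector with the
inverted convention), batch size 128, 350 epochs, focal loss γ=2.  The
first fully-connected layer's width (32) and activation (ReLU) are not
stated in the source and are configurable.

## Evaluation

The confusion matrix (rows true, columns predicted) is reduced
one-vs-rest per class to TP/FP/TN/FN, giving recall, precision,
specificity and F1; overall accuracy is trace/total.  Aggregates are
**support-weighted** means of per-class values — the only standard rule
that makes aggregate recall algebraically identical to overall accuracy
(matching the ACC=RE pattern in the reference tables); the aggregate F1 is
the support-weighted mean of per-class F1, not the harmonic mean of
aggregate precision and recall.  Macro means are also reported.  Any 0/0
cell (a class absent from truth or predictions) is reported as 0 with a
warning flag rather than crashing small-sample reports.

Per-class precision-recall curves are computed at every distinct score
threshold; the area is step-wise average precision `Σ ΔR·P` (no
trapezoidal interpolation, which is optimistic on PR curves).  Prediction
ties break toward the lowest class index.

## Synthetic data

The generator emulates the study conditions without any download: 360 Hz,
250-sample beats of the eight classes, with the database's class
proportions (75,020 / 8,072 / 7,255 / 2,546 / 229 / 150 / 83 / 16) scaled
to any total by largest remainder — at small totals the rarest classes
round to zero, as a small draw from the real distribution would.

Each class is a sum of Gaussian waves (P, Q, R, S, T) whose parameters are
deliberate caricatures of the class morphology: widened R and deep S for
the bundle-branch classes (discordant T for LBBB), a secondary R'
deflection for RBBB, an early peaked P for APC, no P for nodal escape, an
inverted P for nodal premature, and a low slow P with small QRS for atrial
escape.  Per-beat variation is ±3 samples of center jitter and ±10%
amplitude jitter; additive noise is baseline-wander and powerline
sinusoids with random phase plus white Gaussian noise.  The "mild" preset
is 0.10 mV baseline at 0.3 Hz, 0.05 mV powerline at 60 Hz and 0.05 mV
white noise against a 1 mV R-peak.

What this does **not** emulate: rhythm context (RR intervals, multi-beat
patterns), inter-patient morphology variation, electrode artifacts,
class-conditional noise, or any clinically faithful waveform detail.
Tests passing on synthetic data therefore establish that the pipeline's
machinery is correct and that the loss comparison behaves as designed —
not that real-data accuracy will match the reference results, which
require the real database and ~350 epochs of training.

## Problem sizes used by the test suite and acceptance script

Chosen so the full suite runs on one CPU in minutes:

* loss identities on a 10,000-point probability grid;
* gradient checks on H=4 (or 3), T=10 (or 5), batch 2 in float64, against
  central finite differences (tolerance 1e-4 relative);
* metric identity on 1,000 random 8×8 confusion matrices (1e-12);
* pipeline smoke test: 2,000 synthetic beats with database proportions and
  mild noise, H=16, 30 epochs, batch 128, focal γ=2, ≥95% held-out
  accuracy;
* imbalance comparison: 600 normal vs 3 LBBB training beats (200:1),
  balanced 100+100 test set, H=8, 25 epochs, 5 seeds per loss; focal
  minority recall must not trail cross-entropy by more than 1 point.

## Known limitations

* The WFDB reader covers what the MIT-BIH arrhythmia database uses —
  single-segment headers and format-212 signals; other signal formats and
  multi-segment records are rejected with a clear error.
* Training is plain numpy on one CPU; at the full database scale (~84k
  training beats, 350 epochs) it is far slower than the GPU frameworks it
  mirrors, and that headline experiment is not run here.
* The per-beat z-score discards absolute amplitude, which carries some
  clinical information; this follows the reference design.
* Beat-wise splitting lets beats from one recording appear in both train
  and test sets; inter-patient generalization is not measured.
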