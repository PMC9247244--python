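# Methods

`zonewear` re-implements, end to end and on synthetic data, a wearable
pipeline for detecting "the zone" (flow state) of tennis players from
wrist-worn IMU streams labeled live by their coaches.  This note
describes the models, the generator, the numerical choices, and what the
test results do and do not show about real data.

## Problem and pipeline

The observable data for one player-session are a 10 Hz stream of 12
sensor channels — acceleration (3), gravity vector (3), orientation (3),
rotation rate (3) — and a handful of timestamped binary coach labels
("in the zone" / "out of the zone").  The pipeline is:

1. **Cleaning** — duplicate timestamps are removed (first occurrence
   kept) and missing samples on the nominal 0.1 s grid are filled by
   per-channel linear interpolation between the nearest observed
   neighbours, with no extrapolation beyond the observed span.
2. **Label propagation** — each sample takes the most recent coach label
   at or before its timestamp (last-label-carried-forward).  Samples
   before the first label carry no evidence and are excluded rather than
   back-filled.
3. **Windowing** — fixed windows of 50 samples (5 s) stride across the
   stream; a window's target is the propagated state at its *last*
   sample.  The stride is 1 at full scale and 5 in the desk-scale
   profile (a pure compute knob: windows remain 5 s either way).
4. **Splitting** — because the labels are sparse and non-uniform in
   time, train/test splits remove random contiguous sample segments
   (length uniform in [50, 300] samples) into a test pool until test
   windows are ~1/4 of training windows.  Training windows that touch
   *any* test sample are discarded, making the no-leakage guarantee
   absolute; segment draws that unbalance the class ratio between pools
   beyond 0.15 are rejected, and the final plan must have a test/train
   window ratio in [0.18, 0.32].  Five replicate splits are drawn.
5. **Classification** — a stacked LSTM: two layers with 64 and 32
   hidden units, dropout 0.5 after the first layer, an 8-unit ReLU
   dense layer and a single sigmoid output; binary cross-entropy, Adam
   (learning rate 0.0025), batch size 128.  32,401 trainable
   parameters.  Inputs are z-scored per channel with statistics from the
   training windows only.

Four experimental protocols are run over a four-player cohort:
personalized models (1a), one pooled model (1b), leave-one-player-out
generalization (2a), and warm-start transfer (3a), in which each
held-out player's 2a model is retrained on that player's own training
splits with the same splits and seeds as 1a, so the comparison of
epochs-to-80%-threshold between scratch and retrained is paired.
"Epochs to threshold" is the first epoch at which the test accuracy
averaged over the five splits reaches 80%; "N/A" if never.

## The LSTM implementation

The classifier, including backpropagation through time and the Adam
update, is written directly in numpy (float32).  Gate order is
[input, forget, output, candidate]; input and dense kernels are Glorot
uniform, recurrent kernels orthogonal, biases zero except the forget
gate at 1.  The recurrence runs in time-major layout so each per-step
slice is contiguous, and the four gate nonlinearities are evaluated with
a single vectorised sigmoid pass (tanh(x) = 2σ(2x) − 1 for the
candidate block).  Dropout after the first LSTM layer uses one mask per
sequence, shared across timesteps (variational style); per-element masks
behave equivalently here and cost ~60× more to sample.  Correctness is
anchored by a finite-difference gradient check and by the closed-form
parameter count 4·(64·(12+64)+64) + 4·(32·(64+32)+32) + (32·8+8) + (8·1+1)
= 32,401.  Training is bit-reproducible for a fixed seed and thread
count.

## The session generator

No public data accompany the study design, so the generator is a
first-class, tested component that defines the study conditions.

**Latent state.**  A two-state semi-Markov process with
gamma-distributed dwells (shape 2; means 8 min in-zone, 10 min out) —
the simplest process producing sparse alternating labels at a realistic
minute scale.  Sessions start out of the zone.  Session traces are
redrawn (bounded retries) until the realized in-zone time fraction lies
in (0.42, 0.58), implementing the study condition that label ratios are
roughly 50%.  The band must sit inside the chance band of the
generalization task: a held-out player's orthogonal zone signature
projects to ~zero on a model trained on the other players, so that model
falls back to the out-of-zone baseline and scores exactly the held-out
player's majority share, 1 − in_fraction.  Realized fractions outside
the band would make leave-one-player-out look better than chance for
purely compositional reasons.

**Base signal.**  Poisson-timed stroke bursts (0.5 s damped 4 Hz
oscillations on acceleration and rotation-rate channels) riding on a
rally/rest intensity cycle (~40 s period); a unit-norm gravity vector
wandering around (0,0,−1); bounded Euler-like orientation wander
(π·tanh of an Ornstein–Uhlenbeck path — three orientation values rule
out quaternions, and the bounded transform keeps angles in range);
white sensor noise with per-channel scales.  Nuisance correlation times
are deliberately kept below the minimum test-segment length (5 s):
slower drift lets any classifier interpolate labels *through* held-out
segments via the drift state alone — an artefact no contiguous-block
split can remove, which would make even zero-signal data "predictable".

**Zone effect.**  While in the zone the channels receive an additive
modulation, ramped over 2 s at transitions:

* a *personal* constant offset (amplitude 1.4 channel-noise-sds,
  direction per player) plus a small slow personal oscillation
  (amplitude 0.15);
* a *weak shared* zero-mean 0.8 Hz oscillation on a fixed channel
  subset, scaled by `shared_signature_gain` (default 0.25 of amplitude
  0.6) — the "weak shared representation" that warm-start transfer can
  exploit without making players linearly inter-predictable.

The personal offset lives in the 6-dimensional dynamic-channel subspace
(acceleration + rotation rate); gravity and orientation baselines drift
too much to carry a mean offset.  Within a cohort the four offset
directions are made exactly orthogonal (Gram–Schmidt in that subspace):
at the signal-to-noise ratio needed for ≥90% within-player oracle
accuracy, merely *independent* random directions transfer across players
whenever two of them happen to align, which contradicts the
leave-one-subject-out-at-chance property the generator must produce by
construction.  Orthogonality is the exact realisation of "unrelated
signatures" in a four-player cohort.

Amplitudes were calibrated once against a linear-discriminant oracle on
window summary features (per-channel means and standard deviations):
within-player accuracy ≥ 0.90 (observed ~0.93–0.94) and mean
cross-player transfer ≤ 0.60 (observed ~0.47–0.58).  LDA rather than QDA:
the bounded orientation channels violate QDA's Gaussian class-covariance
assumption badly enough to cost ~15 accuracy points where a linear
readout is near-perfect.

**Coaches.**  An observer emits one label per detected transition after
a Gaussian reaction latency (mean 5 s, sd 2 s, clipped at zero), missing
a transition with probability `miss_prob` (default 0).  A *verbose*
coach additionally re-emits the current state every 2.5 min, a *sparse*
coach labels transitions only — reproducing the many-vs-few label-count
pattern between the two games (≥3× more verbose labels on a 75-min
session).  Every label's state equals the latent state at the labeled
moment, and an initial label at t = 0 records the starting state so no
window is ever unlabeled.

**Corruption.**  Raw exports duplicate each sample with probability 0.02
and drop it with probability 0.02 (first/last never dropped), exercising
the cleaning stage; the ground-truth corruption record is kept for
tests.

## Problem sizes (desk-scale profile)

The full-scale configuration (75-min sessions, stride 1, 100 epochs) is
provided but expensive; the default benchmark is a proportionally
scaled-down replica chosen as the package's standard desk configuration:

* sessions 10 min (6,000 samples at 10 Hz, ~24,000 cohort-wide);
* all temporal generator parameters scale by 10/75 — dwell means
  (1.07 / 1.33 min), verbose re-emission (20 s), coach latency
  (0.67 s), rally cycle (~5 s) — so cycles per session, label sparsity,
  the mislabeled fraction near transitions, and the dwell/rally
  separation all match the full-scale conditions;
* stride 5 (~1,200 windows per player), 5 split replicates, 30 epochs
  for tasks 1a/1b/3a, and 5 training seeds at 15 epochs for task 2a
  (2a contributes a final accuracy and the warm-start source models; it
  has no epochs-to-threshold semantics, so its epoch budget is a pure
  compute knob).

Ablation controls run at a further reduced size (stride 10, 10 epochs):
chance-level outcomes do not sharpen with more training, and the
identical-signature control exceeds its 80% bound within a few epochs.

## What passing tests show — and what they do not

The synthetic benchmark shows that the *pipeline* recovers the study's
qualitative findings whenever the data satisfy the generator's
assumptions: strong player-specific zone signatures, a weak shared
component, sparse human labels with reaction latency, near-balanced
states.  It cannot show that real tennis IMU data satisfy those
assumptions — in particular the generator does not emulate biomechanics
of actual strokes, coach disagreement or drift in labeling criteria,
score/match context (no score dynamics are modeled), device artefacts
beyond timestamp duplication/gaps, or more than two latent states.
Accuracy numbers on synthetic data are calibration outcomes, not
evidence about the real task.

## Numerical and design details

* Duplicate policy: first occurrence wins; cleaning is idempotent and
  never alters observed samples.
* Timestamps snap to the nominal grid by rounding t·10 to integers;
  spans are limited to the observed range (no extrapolation).
* Windows straddling a state change take the end-of-window label.
* The splitter rejects segment draws that overlap existing test
  segments; if the pool reaches the target ratio with unbalanced
  classes it drops the segment whose removal best restores balance and
  continues; after 1,000 fruitless attempts it raises an error naming
  the violated constraint.
* Decision threshold 0.5 (classes near-balanced by construction);
  cross-entropy unweighted; no early stopping or LR schedule (fixed
  epoch budget).
* Dropout is train-only; evaluation always runs the deterministic
  forward pass.
* The "All/Avg." report row averages player-level means; its std is the
  across-player standard deviation of those means, which is why it can
  exceed any player's split-std.
* Task 2a has no split replicates (testing uses *all* of the held-out
  player's windows); its variance comes from training seeds.
* Chance bands in tests are wider than a naive binomial interval on the
  window count: windows overlap (stride < window) and share dwell
  segments, so they are far from independent Bernoulli trials.

## Known limitations

* The LSTM is numpy on one CPU; full-scale runs (stride 1, 100 epochs,
  75-min sessions) take hours, not minutes.
* The generator's zone effect is additive and stationary within a
  session; real signatures plausibly drift.
* With more than six players the exact-orthogonality construction for
  offset directions saturates the dynamic subspace and would need a
  lower-coherence design instead.
* Coach notes are decorative strings; their content is not modeled.
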