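# Methods

This note documents the models, signal-processing choices, synthetic-data
design and numerical conventions behind `mmh-har`. It is the package's own
account of what is computed and why; every number quoted here is produced
by the code (tests or the acceptance script), not asserted from elsewhere.

## Problem setting

Seven manual-material-handling (MMH) activities are classified from a
10-channel wearable recording: 8 kinematic signals (chest/shoulder/elbow/
knee flexion; hand front-relative position and acceleration; pelvis
transversal-plane velocity; pelvis global vertical position) sampled at
240 Hz, plus the RMS envelopes of 2 surface-EMG channels (biceps brachii,
brachioradialis). The classes are N-pose (N), Lifting from the Floor (LF),
Keeping lifted (K), Placing on the Table (PT), Lifting from the Table
(LT), Carrying (W) and Placing on the Floor (PF), integer-encoded 0..6 in
`mmh_har.activities`.

Early fusion stacks the 10 channels into one matrix; the stream is cut
into non-overlapping 1 s windows (10 × 240), each carrying a single class
label. All networks consume these windows.

## sEMG conditioning chain

Raw sEMG (synthetic rate 2000 Hz) is processed at its native rate, then
aligned to the 240 Hz kinematic clock:

1. **Notch, 50 Hz** — zero-phase IIR notch, Q = 25. The quality factor is
   chosen so a 2 s mains probe is attenuated ≥ 20 dB *including* the
   forward–backward filter's edge transients, while a 5 Hz probe passes
   within 0.1 % RMS.
2. **Band-pass, 20–500 Hz** — 4th-order Butterworth, zero-phase
   (`sosfiltfilt`). Order and phase handling are package choices: zero
   phase preserves alignment between the envelope and the label stream.
3. **Full-wave rectification.**
4. **MVC normalization** — division by the subject's maximum voluntary
   contraction calibration value stored with the session.
5. **RMS envelope, 250 ms** — centered sliding window; at the edges the
   window shrinks to the available overlap rather than fabricating padded
   values. The implementation is checked to < 1e-9 against a naive
   O(n·w) per-sample oracle.
6. **Resampling to 240 Hz** — polyphase (`resample_poly`, `padtype="line"`),
   downsampling only. Processing must precede alignment because the
   20–500 Hz band cannot exist at 240 Hz.

Windows spanning an activity transition take the majority label; ties go
to the label of the window's center sample (and to the lowest class code
if the center label is not among the tied leaders).

## Class balancing

MMH streams are dominated by the neutral pose. The training portion (never
the test portion — balancing test data would bias macro-F1) is equalized
to the median class count: larger classes are down-sampled uniformly
without replacement; smaller classes are topped up by replicating segments
round-robin with additive white Gaussian noise, per-channel sd =
0.05 × that channel's within-segment sd. Relative noise scaling respects
the heterogeneous channel units (degrees vs. metres vs. normalized EMG);
0.05 is small enough to preserve class geometry and large enough to deter
memorization. Originals always survive bit-identical.

## Architectures

All five networks are declared as `ArchitectureSpec` layer lists; the
runtime model and the complexity profiler consume the same spec, so shapes
and parameter counts cannot diverge.

* **BiLSTM** — sequence input (10 features × 240 steps) → bidirectional
  LSTM(h) emitting the last step per direction → dense(2h→7) → softmax.
* **Sp-DAE** — the flattened 2400-sample window → log-sigmoid encoder(h)
  → linear decoder, trained unsupervised to reconstruct the *clean* input
  from a Gaussian-corrupted copy (corruption sd 0.05 on standardized
  inputs) under the sparse-MSE objective below; the decoder is then
  discarded and dense(h→7) + softmax is trained supervised on top of the
  encoder. A linear decoder is used because the standardized inputs are
  not confined to (0, 1).
* **Recurrent Sp-DAE** — the pre-trained encoder maps each window to one
  feature vector, which a BiLSTM consumes as a length-1 sequence
  (per-window features; a per-timestep wiring would change the encoder's
  input dimension and is not the default).
* **RCNN** — the window as a 10 × 240 image inside a sequence-fold/unfold
  pair: conv2d(32, 3×3, stride 1×1, dilation 1×1, valid) → instance norm
  → ReLU → conv2d(32, 3×3, stride 1×4, dilation 2×2, valid) → instance
  norm → ReLU → flatten → GRU(h) → dense → softmax. Valid convolution
  sizes follow out = ⌊(in − (k−1)·d − 1)/s⌋ + 1: the maps are 8×238×32
  and 4×59×32.
* **DeepConvLSTM** (benchmark) — four valid temporal convolutions (64
  maps, 5-wide along time) shrink 240 → 224; the width axis is then read
  as time with 64 × 10 = 640 features per step, feeding two stacked
  LSTM(128) layers, dense and softmax.

Gate conventions (needed for exact parameter accounting): LSTM gate order
(input, forget, cell, output) with one bias vector per gate block,
parameters 4h(d+h+1) per direction; GRU order (reset, update, candidate)
with the reset gate applied to the recurrent product,
n = tanh(Wₙx + bₙ + r⊙(Rₙh)), parameters 3h(d+h+1). With these
conventions the BiLSTM with 300 hidden units has
8·300·10 + 8·300² + 8·300 + 601·7 = 750,607 learnable parameters.

## Training

Cross-entropy is minimized with Adam (batch 128, initial learning rate
1e-3, L2 coefficient 1e-4) under the piecewise-constant schedule
lr_t = 1e-3 × 0.1^⌊epoch/10⌋. The schedule is implemented exactly as
stated; for epoch counts in the thousands it underflows to numerically
zero learning rates, so `TrainConfig.lr_floor` can cap it (off by
default). Inputs are standardized per channel with statistics estimated on
the training set only; the statistics travel with the model. Weights are
Glorot-uniform, seeded; training is deterministic given the seed on a
fixed device. A single-class training set and non-finite losses raise
named errors.

The networks are executed by a small numpy runtime written for this
package (forward and hand-derived backward passes for dense, LSTM, GRU,
bidirectional wrappers, strided/dilated valid conv2d, instance norm,
ReLU). Every backward pass was verified against central finite
differences; the recurrent forward passes are pinned to straight-line
per-timestep reference implementations in the test suite.

Sp-DAE pre-training minimizes

  L = mean‖x̂ − x‖² + λ Σ w² + β Σᵢ KL(ρ ‖ ρ̂ᵢ),
  KL(ρ‖ρ̂) = ρ ln(ρ/ρ̂) + (1−ρ) ln((1−ρ)/(1−ρ̂)),

with ρ = 0.05, β = 1, λ = 1e-4, ρ̂ᵢ the mean activation of hidden unit i
(clamped to [1e-12, 1−1e-12] with a logged warning). The optimizer is
scipy's nonlinear conjugate gradient (`method="CG"`) with the analytic
gradient; full-batch Adam is available as a documented fallback.

## Complexity accounting

`mmh_har.complexity` computes, per layer and in closed form:

* **LP** — dense: (d+1)·o; conv2d: (kh·kw·cin+1)·F; instance norm: 2c;
  recurrent: G·h·(d+h+1) per direction (G = 4 LSTM, 3 GRU).
* **MAC** — multiplications inside dot products: dense d·o; conv
  kh·kw·cin per output element; recurrent G·h·(d+h) per timestep per
  direction, every timestep counted uniformly (the first steps see zero
  states but perform the same arithmetic).
* **MA** — all scalar multiplications and additions: dot products, bias
  and gate-combination adds, elementwise gate arithmetic (LSTM: 3h mults
  + h adds per step; GRU: 3h mults + 2h adds), and instance-norm
  statistics (3N mults, 4N−2 adds per channel of N spatial elements).
  Transcendental activations, divisions, square roots and the softmax are
  excluded.

The MAC/MA convention is self-defined and pinned by an instrumented
scalar-loop forward pass in the tests (30 random tiny specs must agree
operation-for-operation); it is intentionally *not* reverse-engineered
from any published totals, which could not be reconciled with these
layer stacks under standard conventions. Parameter memory uses 4
bytes/parameter with the MiB convention (1 MB = 1,048,576 bytes) — the
unique pairing that maps 750,607 parameters to 2.863 MB. Latency is
estimated as MA / (attainable rate × 0.7), the 0.7 being an empirical
kernel-efficiency factor; the default attainable rate (8 Gops/s) stands
for a small embedded x86 CPU and is a reporting convention, not a
measurement.

## Synthetic data

`mmh_har.synth` generates labeled multi-rate cohorts with the statistical
structure the pipeline needs to be testable end-to-end:

* **Kinematic motifs** — fixed analytic primitives per class, scaled by a
  per-subject amplitude: half-cosine flexion excursions with a pelvis
  drop for the floor-level lifts/placements (LF, PF), smaller excursions
  with distinct joint mixes for the table-level ones (PT, LT), a smoothed
  boxcar of sustained elbow flexion for holding (K), sustained pelvis
  transversal velocity with a gait oscillation for carrying (W), and a
  noisy baseline for N-pose.
* **sEMG** — a zero-mean band-limited (20–450 Hz) stochastic carrier
  multiplied by an activation envelope tanh(act · gain · (0.15 +
  0.06·load)) · MVC: amplitude grows monotonically with the handled load
  and saturates below the MVC. A 50 Hz mains component (2 % of MVC) and
  white sensor noise are added so the notch and band-pass stages have
  real work to do.
* **Subjects** — per-subject amplitude scale U(0.85, 1.15), sEMG gain
  U(0.8, 1.2), MVC U(0.5, 1.5), channel noise U(0.03, 0.07), drawn
  deterministically from the master seed.
* **Imbalance** — the protocol is padded with a trailing N-pose rest so
  the N share meets a configurable floor (default 0.5), reproducing the
  dominant-neutral-class structure.

What the generator does *not* emulate: real biomechanics (no dynamics, no
inter-joint consistency), sensor-fusion artifacts, electrode shift,
fatigue drift, or between-class confusability beyond additive noise. The
classes are separable by construction — with noise → 0 a nearest-centroid
classifier on window means is already near-perfect — so passing training
tests demonstrates that the pipeline, optimizer and protocols work, not
that these architectures would reach any particular score on real
recordings.

## Study fixture and problem sizes

The end-to-end checks run on a 6-subject cohort, 8 protocol cycles per
subject (~4 min of activity each, ~1,860 windows total, N share ≥ 0.5),
master seed 42. These sizes were chosen so that a BiLSTM with 32 hidden
units trained for 30 epochs has enough gradient steps to converge on the
separable fixture while the whole suite stays comfortably inside a
single-CPU run: the 70–30 training takes about a minute and the 6-fold
LOSO about seven minutes. Hyperparameter sweeps and subject-increment
curves are exercised at reduced scale (tiny grids, 1-epoch cells) — the
full-scale grids of hundreds of trainings are out of scope by design.

## Evaluation

Macro-F1 is the headline metric (unweighted mean of per-class F1; a class
absent from both truth and predictions scores 0 with a logged warning).
Accuracy and macro-precision accompany it; micro-F1 equals accuracy for
single-label problems and is used as an identity check. The 70–30 split
is stratified by class at the window level (documented as optimistic
relative to subject-level splits), deterministic per seed; classes with a
single segment stay whole in the training portion. LOSO produces exactly
one fold per subject and asserts zero subject leakage in every fold;
subject-increment curves re-draw both the split and the initialization
across repeats.

## Known limitations

* The numpy runtime is single-threaded-BLAS fast, adequate for the study
  sizes here, but not for thousand-epoch trainings of 300-unit networks.
* Synthetic separability means recognition scores on this fixture are
  ceilings of pipeline correctness, not estimates of real-world accuracy.
* MAC/MA totals are convention-bound; compare them only within this
  package's convention.
* The Sp-DAE conjugate-gradient path is full-batch and therefore memory-
  bound for very wide encoders; the Adam fallback exists for that case.
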