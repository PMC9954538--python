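# Methods

This note documents the models, conventions and numerical choices behind
`eegtrm`, the open design decisions that were made, and what the test suite
does and does not establish.

## The topographic representation module

**Model.** An EEG epoch is a matrix X ∈ ℝ^{C×TP}.  Given a montage
assigning each channel c an injective grid cell (r_c, q_c) on an H × W
grid, the mapping block produces a stack T ∈ ℝ^{H×W×TP} with
T[r_c, q_c, t] = X[c, t] and all other entries exactly 0.  No scaling or
interpolation is applied: the module's premise is that the *network* should
learn spatial structure, so the representation itself stays lossless
(`unmap(map(X)) = X` bit for bit) and sparse.  Zero-fill rather than
interpolation is a deliberate, fixed choice; no interpolation mode exists.

**Kernel schedule.** The convolution block applies stride-1, padding-free
2-D convolutions to each time slice until the spatial extent is 1 × 1.
With base kernel k, the rule at feature-map size (h, w) is:

- if h > k or w > k: use kernel (min(k, h), min(k, w));
- otherwise: use kernel (h, w), which terminates the stack.

"Larger than k × k" is read as *at least one dimension strictly exceeds k*;
this is the reading under which the closing kernels may be asymmetric (for
a 7 × 9 grid with k = 3 the schedule is (3,3), (3,3), (3,3), (1,3)).  Each
layer maps (h, w) → (h − k_h + 1, w − k_w + 1); since each step strictly
shrinks at least one dimension, the schedule terminates for every finite
grid (the suite sweeps all grids up to 32 × 32).  Every layer outputs C
feature maps; layer 1 has one input channel (the topographic map itself).

**Time handling.** The convolutions are strictly spatial.  Time is folded
into the batch axis, so every time point is processed identically and
independently; the module is therefore exactly equivariant to permutations
of time points, which the suite asserts.

**Bias/normalization policy and parameter accounting.** The default policy
is: no additive bias on any convolution, and one batch-normalization layer
with learned affine scale/shift (2C parameters) after the full stack.
Under it the trainable-parameter total is

  C·k₁ₕ·k₁ᵥ + Σ_{l≥2} C²·kₗₕ·kₗᵥ + 2C.

This is the unique simple policy reproducing all four reference totals
(46,860 / 18,612 / 64,130 / 35,332) for the shipped layouts; per-layer
affine normalization or per-layer convolution biases each add 2C or C per
layer and break the 4-layer totals.  Both alternatives remain available via
`norm_policy` and `conv_bias` but are non-default.  Batch-norm running
statistics are buffers, never counted as parameters.  `count_parameters` is
a closed form; the suite requires it to equal brute-force enumeration of
the assembled module's trainable arrays on the reference configurations and
on random (H, W, C, k, policy) instances.

**No internal nonlinearity.** The TRM stack is linear apart from
normalization by default; an optional ELU between layers can be enabled and
does not change parameter counts.

**Initialization.** Uniform fan-in (±1/√fan_in) from a seeded generator;
identical seeds give bit-identical modules and training trajectories.

## The numpy layer stack (`eegtrm.nn`)

All trainable computation runs on a small hand-written layer library:
`Conv2d` (stride 1, valid or explicit/same padding), `DepthwiseConv2d`,
`BatchNorm2d`, average/max pooling, ELU/square/log nonlinearities, dropout
with inverted scaling, dense layers, softmax cross-entropy, and Adam with
L2 weight decay added to the gradient.  Backward passes are written by hand
and validated against central-difference numerical gradients (atol 1e-7 on
tiny instances).  Arrays are float64 throughout — chosen for exactness of
the parameter accounting and test reproducibility over speed.  Input
gradients of convolutions are accumulated per kernel offset so memory stays
proportional to the activation size.  The safe-log nonlinearity clips at
1e-6 before the logarithm.

## Backbones

Three reference architectures are reimplemented minimally, at their
published default hyperparameters, as contract-conforming consumers of
(batch, C, TP) input returning (batch, n_classes) logits:

- **shallow**: 40-filter temporal convolution (kernel 1×25), 40×40 spatial
  convolution across all channels, batch norm, squaring, average pooling
  (1×75, stride 1×15), log, dropout 0.5, dense classifier.  Minimum TP 99.
- **deep**: four convolution/max-pool blocks (25/50/100/200 filters,
  temporal kernels 1×10, pools 1×3), the first block split into temporal and
  spatial convolutions; batch norm + ELU per block; dense classifier.  For
  inputs too short for the standard cascade, per-block temporal kernels and
  pools shrink to the largest sizes that fit; the resolved cascade is
  recorded on the instance (`.architecture`).  The exact adjustment used in
  prior work for short inputs is not published, so the largest-fitting
  cascade is this package's own choice.
- **compact**: depthwise/separable design (F1 = 8, D = 2, F2 = 16, temporal
  kernel 64 same-padded, separable kernel 16), no hidden dense layer.
  Minimum TP 32.  At the 55 × 280 scale it has ≥ 10× fewer parameters than
  the other two, which the suite asserts.

Softmax lives inside the loss, not the network; accuracy is argmax-based
and unaffected.  Bit-exact replication of any third-party implementation's
initialization or dropout schedule is a non-goal; the contracts (shapes,
parameter counts, trainability, chance-level behavior untrained) are what
is tested.

## Synthetic data

The generator emulates the one property the TRM is designed to exploit:
class-conditioned *spatially localized* oscillatory activity.  Each class
owns a focus cell (greedy max-min placement over assigned cells,
deterministic); each trial carries one sinusoidal burst with frequency
drawn uniformly from the oscillation band (default 8–13 Hz), uniform random
phase, and a Hann envelope over the epoch, projected onto channels with
Gaussian gain exp(−d²/2σ²) in *grid-cell* distance d (σ =
`spatial_spread`, default 1.0).  Spatial decay is measured on the grid, not
in scalp arc length, because the grid is all the TRM ever sees.

Noise is a shared 1/f-shaped component (spectral shaping of white noise
with power exponent 1.0, 30% amplitude — a crude common-mode term) plus
independent white noise per channel, scaled per trial so that the mean
signal-to-noise power ratio equals `snr` (default 5, linear; ∞ = noiseless).

Defaults (2 classes × 40 trials, 280 samples at 200 Hz, snr 5, spread 1.0)
mirror the small within-subject evaluation scale the package targets.

**What passing tests do not show.** The generator has no artifacts, no
nonstationarity, no inter-trial latency jitter, no volume-conduction
mixing beyond the common-mode term, and its class difference is *purely*
spatial.  Networks separate it almost perfectly even at very low SNR, so
training results here demonstrate correctness of the pipeline (shapes,
gradients, checkpointing, determinism, the ability to exploit spatial
structure), not expected accuracy on real recordings.

The event-stream fixture embeds stimulus/response marker pairs (gap uniform
in 20–40 s by default, reaction delay uniform in 0.3–0.8 s) in continuous
noise, for exercising the epoching rules.

## Preprocessing

- **Target epochs**: window −1300…+200 ms around each response marker;
  per-segment baseline correction subtracts the mean of the first 100 ms.
  The stated ingredients are a 1500 ms window at 200 Hz (300 samples) yet
  a 280-sample evaluation shape; the only reading that reproduces 280 from
  those ingredients is discarding the baseline span after correction
  (1400 ms → 280 samples), so `discard_baseline=True` is the default and
  the alternative (300 samples) stays configurable.
- **Nontarget epochs**: 1500 ms windows, 500 ms step, admissible only when
  the whole window keeps ≥ 3000 ms distance from *every* marker (stimulus
  and response; the exclusion is symmetric).  Balancing subsamples
  uniformly with the config seed.  Admissibility is computed by direct
  interval tests; the suite checks the resulting counts against an
  independent interval-arithmetic enumeration on random marker layouts.
- **Trialwise epochs**: the full cued trial from onset (4 s at 250 Hz →
  1000 samples); no baseline handling.
- **Bandpass/downsample**: Butterworth order 4, applied forward–backward
  (zero phase), then polyphase resampling.  The filter family is not
  dictated by the protocol being mirrored; order-4 Butterworth is this
  package's choice.  A band edge exactly at the post-resampling Nyquist
  frequency is allowed (the 4–125 Hz @ 250 Hz setting requires it).
  Segments whose window leaves the record are skipped with a warning, not
  an error.

Channel exclusion is by name, order-preserving; channel matching between
epochs and montages is always by name, never by position.

## Training and evaluation protocol

Adam (lr 1e-3 = optimizer default, weight decay 1e-3 added to gradients),
softmax cross-entropy, batch size 32, default 300 epochs.  Validation loss
is evaluated once per epoch after the training pass; the model state is
checkpointed on strict (`<`) improvement only, and the checkpointed state
is restored before testing, so reported accuracy always comes from the
minimum-validation-loss epoch.  Folds with non-finite loss are excluded
from means with a loud warning, never silently imputed.

Split schemes: `cv4` partitions trials into four stratified quarters
(shuffled by default; contiguous quarters available via `shuffle=False`);
fold i tests on quarter i and validates on quarter (i+1) mod 4 — the
rotation is unspecified territory and this fixed choice is logged by being
deterministic.  `fixed-test` keeps the given test indices and draws a
stratified seeded 80/20 train/validation split from the remainder per
repeat.  Stratification by label is enforced in both modes to keep small
synthetic runs non-degenerate.

`compare` computes the two-tailed paired t statistic in closed form
(t = d̄ / (s_d/√n), s_d with ddof 1) with the p-value from the t
distribution; the suite requires agreement with an independent full
implementation (`scipy.stats.ttest_rel`) to 1e-10 on random vectors.
Identical vectors give p = 1; zero-variance nonzero-mean differences are
degenerate (p undefined, NaN, flagged).

A soft expectation, documented rather than gated: on spatially structured
data at moderate SNR, TRM variants tend to reach validation losses at least
as low as their originals on a majority of seeds.  Because the synthetic
task saturates easily, the suite does not assert this as a hard test.

## Problem sizes in the shipped tests

Unit and property tests run on small montages (3 × 4, 6 channels) and short
epochs; the full-scale checks use the real layout sizes (55 × 280 mapping
and parameter accounting, and one 30-epoch training run of the shallow
backbone with a TRM-(5,5) on 80 trials of 55 × 280).  These sizes are the
package's chosen verification scale: large enough to hit every contract at
the reference dimensions, small enough that the whole suite runs in a few
minutes on one CPU.

## Known limitations

- Training is CPU/numpy; it is meant for protocol-scale experiments and
  verification, not for full-dataset GPU-scale benchmarking.
- Cross-subject transfer is out of scope.
- The shipped montage YAMLs guarantee grid size and channel count; per-cell
  placements approximate the usual scalp layout and are meant to be edited.
- Raw BBCI `.mat` dialects are not parsed; continuous input arrives as EDF
  (via MNE) or the documented NPZ/HDF5 containers.
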