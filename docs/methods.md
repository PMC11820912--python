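# Methods

This note documents the modelling choices, parameters and numerics of the
pipeline, and what the synthetic benchmarks do and do not establish.

## Problem setting

Each instance is a 30-minute, 1 Hz, three-channel window (heart rate, skin
conductance, acceleration magnitude) ending immediately before one ESM
prompt, labelled by that prompt's self-report: the binary PANAS category
(positive-item sum vs negative-item sum; equal sums are undefined under
the larger-sum rule, so tied prompts are excluded and counted rather than
force-assigned, which would bias the class balance), the raw 1–5 valence
and arousal ratings as 5-class targets, and their 1–3 vs 4–5
binarisation. Generalisation is measured across people: train and test
sets never share a subject, because within-subject temporal correlation
would otherwise inflate every score.

## Signal conditioning

Order of operations per modality: magnitude (ACCEL only) → decimation →
per-subject z-scoring → LMS denoising → median smoothing → windowing.

* **Magnitude and quantisation.** `√(ax²+ay²+az²)`, quantised to 1/2048 g
  (the device resolution); quantisation is applied after the square root,
  treating the magnitude as the device-reported quantity.
* **Decimation.** Every-nth-sample selection (GSR n=40, ACCEL n=20) onto
  the 1 Hz HR grid. The retained phase is index 0 by default and is a
  config knob; nothing downstream depends on the phase beyond a sub-second
  alignment shift.
* **Standardisation.** Per subject and modality over the whole recording,
  before filtering, so the LMS step size has a fixed scale and model
  inputs are comparable across subjects. It is switchable
  (`standardize=False`) for strictly causal processing, since a global
  mean/variance uses future samples.
* **LMS adaptive noise cancellation.** No external noise reference exists
  in a single-channel stream, so the standard single-channel reading is
  used: an adaptive line enhancer. An `order=8` FIR filter predicts the
  current sample from the signal delayed by `delay=1` samples, weights
  updated by `w ← w + μ e x` with `μ=0.01` on z-scored input; the
  *prediction* (the temporally predictable, band-limited component) is the
  cleaned output, the error term carries broadband noise and is dropped.
  With `μ=0` the weights never move and the output is the frozen initial
  prediction (identically zero for zero-initialised weights). A weight-norm
  bound (1e6) turns divergence into an explicit error naming the step
  size. An acceleration-as-reference mode (`reference="external"`) is
  provided for motion-artifact cancellation but is unvalidated.
* **Median filter.** Kernel 3, centre-aligned, edges replicated
  (`scipy.ndimage.median_filter`, `mode="nearest"`). The centred kernel
  looks one sample ahead; because the line enhancer predicts from a one-
  sample delay, the composed filter chain is still causal sample-for-
  sample (verified by a property test). The final window sample may use
  the sample at the prompt time itself through edge handling — a
  sub-second horizon that is irrelevant at the 30-minute window scale.
* **Gaps and windows.** Missing stretches are kept as explicit gap runs
  (start, length) on the sampling grid with NaN placeholders — never
  silently interpolated. Filters run on interpolation-filled copies so
  their state stays finite, and gap positions are restored to NaN
  afterwards. A window is kept only if its per-column completeness
  reaches the threshold (default 1.0, i.e. fully observed); with a lower
  threshold, residual holes are linearly interpolated and the
  completeness fraction records the fact.

## Architecture

Per modality, a two-layer temporal CNN (kernels 7 and 5, stride 2 each,
ReLU, hidden width `cnn_hidden`) maps the length-T channel to T/4 × `d_E`
embeddings. Embeddings are concatenated in fixed (HR, GSR, ACCEL) order
and linearly projected to the encoder width `d`; the reference
configuration uses `d_E=128`, `cnn_hidden=128` and `d=512`, reading the
"512-dimensional" fused vector as the post-projection width since
512 is not divisible by three modalities. Sinusoidal positional encodings
are added at the fused width. Each encoder layer computes
`H' = FFN(MultiHead(H)) + H` — deliberately a *single* residual around the
composed attention + feed-forward branch, as specified, rather than the
more common two-residual layout — followed by a post-residual LayerNorm
that can be disabled (`layer_norm=False`) to recover the bare equation for
algebraic tests. Pooling is a temporal mean by default; a learned CLS
token is available. The head is a linear layer with softmax, trained with
categorical cross-entropy (logs clamped at 1e-12).

The "inner dimension" hyperparameter explored in the sweep (values
4/8/16) is interpreted as the number of attention heads — the standard
Transformer knob with that range — and kept a free config key so
alternative readings remain runnable.

Everything is float64 NumPy with hand-written backward passes; analytic
gradients agree with central finite differences to ≤1e-4 relative error
(checked over all parameter groups). Finite-difference checks are done at
a generic point: zero-initialised biases put ReLU pre-activations exactly
at the kink, where the subgradient and a one-sided difference
legitimately disagree.

## Optimization protocol

Adam with β₁=0.9, β₂=0.999, ε=1e-8; learning rate `lr0·(1 − e/E)` from
`lr0=1e-3` over `E=100` epochs; L2 coefficient 1e-5 added to the gradient
in the optimizer; dropout 0.2 on the embedding and on each encoder
branch; batch size 32 by default (the sweep's best region; 64 is a valid
override). Early stopping halts after 10 consecutive epochs without
validation-accuracy improvement. The validation set is a subject-wise 10%
carve-out of the training side (at least one subject) — never the test
set, which would leak. The checkpoint kept is the best validation
accuracy with ties broken toward the lower training loss: with a small
validation set the accuracy saturates within a few epochs, and
first-achievement checkpointing would freeze a barely-trained model.

One integer seed fans out to the subject split, validation carve, weight
initialisation, dropout and batch shuffling; runs are bit-reproducible in
serial execution.

### Metrics

Accuracy, macro precision and macro F1 in percent; confusion matrices are
row-normalised (each cell the proportion of that true label). Per-class
precision/recall are 0 when undefined by empty prediction/support for a
class that occurs at all; a class absent from both truth and prediction
is excluded from macro means with a warning (scoring it zero is a config
option). Single-modality and pairwise ablation cells instantiate only the
named branches rather than zero-masking a full model, so parameter count
scales with the input.

## Synthetic studies

The generator emulates the shape of a multi-day ambulatory study. Default
desk-scale conditions: 12 subjects × 1 day × 10 prompts inside a 4-hour
daily wear block, 300 s pre-prompt windows (the 4-hour block and 300 s
window are reduced stand-ins for a waking day and the 30-minute protocol
window; prompts are placed in disjoint per-day slots so windows never
overlap). Per prompt a latent state `s ~ Bernoulli(0.5)` is refined to a
level `L` (uniform on {4,5} if positive, {1,2,3} if negative), giving a
balanced binary task by construction; the drive `(L−3)/2` scales all
effects during the pre-prompt window.

| parameter | default | meaning |
|---|---|---|
| `hr_shift` | 8 bpm | HR offset at full drive |
| `gsr_event_rate_ratio` | 3 | phasic-event rate ratio, positive vs negative |
| `accel_var_ratio` | 2 | motion-variance ratio |
| `hr_sigma`, `gsr_sigma`, `accel_sigma` | 3 bpm, 0.05 μS, 0.05 g | white-noise levels |
| `artifact_rate_per_hour` | 10 | spike artifacts per stream |
| `gsr_event_rate` | 2 /min | baseline phasic-event rate |

HR adds a 65 bpm baseline, per-subject offset and a slow sinusoidal
drift; GSR is a tonic level plus exponentially decaying phasic bumps
(Poisson arrivals, τ=4 s) quantised to 0.01 μS; ACCEL is gravity plus a
shared smoothed activity latent across three axes at 1/2048 g. ESM items
are drawn around level-dependent means, so PANAS labels recover the
latent state with a small (<~3%) flip rate at borderline levels; valence
and arousal both equal `L` (one latent drives both, so the two 5-class
tasks are equally informed). `SimConfig.null()` zeroes every effect,
severing streams from labels.

What this shows — and does not. Passing the planted-effect benchmark
(binary accuracy ≥90%, 5-class well above the 20% chance level, null runs
at chance) demonstrates that the pipeline extracts state-dependent
physiological structure and does not leak labels. It does *not*
demonstrate performance on real recordings: the generator has
piecewise-stationary Gaussian/Poisson components, a single latent behind
all modalities and labels, no circadian structure, no sensor dropout
beyond point spikes, and far stronger effects than real affect
physiology. Accuracies on synthetic runs are not comparable to accuracies
on field data.

## Known limitations

* Heart rate is consumed as a 1 Hz stream; deriving it from raw PPG is
  out of scope.
* The on-disk CSV schema is an assumption isolated in the io module;
  other layouts need only a new reader.
* The NumPy network is serial and desk-scale; the reference-width
  configuration (d=512) trains slowly on one CPU and is intended for
  completeness, not throughput.
* No tonic/phasic GSR decomposition, HRV features or motion-artifact
  segment rejection beyond the completeness threshold.
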