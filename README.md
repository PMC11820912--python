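# wearaffect

Affective-state recognition from multi-day wrist-worn physiological
recordings. The package targets ambulatory studies in which participants
wear a wrist device recording heart rate (HR, 1 Hz), galvanic skin response
(GSR, 40 Hz) and tri-axial acceleration (ACCEL, 20 Hz) over several days
while answering experience-sampling (ESM) questionnaires — a ten-item PANAS
short form plus single-item valence and arousal ratings, each on a 1–5
scale — at random moments of daily life. The goal is to predict the
self-reported affective state from the 30 minutes of physiology preceding
each prompt. It is written for affective-computing and mental-health
researchers who want a transparent, fully testable reference pipeline.

## What it does

**Labels.** The four positive-affect items (inspired, active, determined,
attentive) are summed against the six negative-affect items (upset,
hostile, alert, ashamed, nervous, afraid); the larger sum defines the
binary PANAS class (ties are excluded and reported). Valence and arousal
ratings define 5-class targets directly, and a collapsed binary variant
(ratings 1–3 vs 4–5) is also provided.

**Preprocessing.** ACCEL is reduced to its Euclidean magnitude
`√(ax²+ay²+az²)` at 1/2048 g precision; GSR and ACCEL are decimated to the
1 Hz HR grid by every-40th / every-20th sample selection; each stream is
z-scored per subject, denoised by LMS adaptive noise cancellation
(an adaptive line enhancer: an FIR predictor with weight update
`w ← w + μ·e·x` against the signal's own delayed copy) and smoothed with a
kernel-3 moving median; the `T = 1800` samples before each prompt form a
`T×3` segment.

**Model.** Per-modality temporal-CNN extractors produce `T′×d_E`
embeddings that are concatenated (`E = [E_HR; E_GSR; E_ACCEL]`), projected
to width `d`, summed with sinusoidal positional encodings
`P(i,2j) = sin(i/10000^{2j/d})`, `P(i,2j+1) = cos(i/10000^{2j/d})`, and
passed through encoder layers
`H^{l+1} = FeedForward(MultiHead(H^{l})) + H^{l}` built on scaled
dot-product attention `softmax(QKᵀ/√d_k)V` with `h` heads re-projected by
`W_O`. Temporal mean pooling feeds a softmax head
`ŷ = softmax(W_out E_final + b_out)` trained with categorical
cross-entropy `L = −Σ_c y_c log ŷ_c`. The network is implemented in NumPy
with hand-written analytic gradients (verified against finite differences).

**Protocol.** Splits are by subject (no participant on both sides), Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with lr decaying linearly from 1e-3,
L2 1e-5, dropout 0.2, ≤100 epochs, early stopping after 10 stale epochs on
a subject-wise validation carve-out. Metrics: accuracy, macro precision,
macro F1, row-normalised confusion matrices; runners cover the
modality-combination ablation and the batch-size × inner-dimension grid.

**Synthetic studies.** `wearaffect.synthetic` generates whole studies with
a known latent affect level driving HR shifts, Poisson GSR phasic-event
rates and motion variance, so every stage is testable offline with ground
truth — including a null mode in which the streams carry no label
information at all.

## Worked example

```python
from wearaffect.experiments import run_desk_experiment

results, report = run_desk_experiment(0, task="panas_binary")
print(results.summary(report))
```

```
                  Affective-state classifier
==============================================================
Task:                   panas_binary
Modalities:             hr+gsr+accel
Encoder:                2 layers, 4 heads, width 32
Parameters:             20154
Training subjects:      10
Epochs run:             21 (best epoch 11)
Best val accuracy:      100.00%
Final train loss:       0.0415
Optimizer:              Adam lr0=0.001 wd=1e-05 batch=32
--------------------------------------------------------------
Test accuracy:          95.00%  (n=20)
Macro precision:        95.83%
Macro F1:               94.88%
==============================================================
```

This simulates a 12-subject study with a strong planted effect (8 bpm HR
shift, 3× GSR event rate in positive states), conditions the signals,
trains on 10 subjects and tests on the 2 held-out ones: 19 of the 20
held-out prompts are classified correctly. With
`sim_cfg=SimConfig.null()` the same call yields chance-level accuracy,
because the null generator removes every physiological effect while
keeping the labels.

The same stages are available as a CLI:

```bash
wearaffect simulate --out data/ --seed 0
wearaffect preprocess --raw-dir data/ --esm data/esm.csv --out segments.h5
wearaffect label --esm data/esm.csv --out labels.csv --report report.json
wearaffect train --archive segments.h5 --task panas_binary --out run/
wearaffect ablate --archive segments.h5 --tasks panas_binary --out ablation.csv
```

## Documentation

`docs/methods.md` describes the generative model, every tunable parameter
with units and defaults, the numerical choices made where the underlying
method is ambiguous, and what the synthetic benchmarks do and do not show
about real recordings.
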