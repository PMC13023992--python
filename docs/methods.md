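# Methods

This note documents the models, numerical choices and known limitations of
`tfrim-sad`. It is the package's own account of its science; every number
quoted here is computed by the test suite or by `scripts/acceptance.py`.

## Problem

Small airway dysfunction (SAD) is conventionally diagnosed from forced
spirometry: the ratios v_k of measured to predicted FEF25–75, FEF50 and FEF75
are compared against the clinical cutoff 0.65, and a subject is labelled SAD
when at least two of the three fall below it. Forced manoeuvres are
effort-dependent; impulse oscillometry (IOS) needs only tidal breathing. The
package implements an IOS-based pipeline that (1) converts a raw two-channel
IOS recording (oral pressure in kPa, flow in L/s, 400 Hz) into a
Time–Frequency Respiratory Impedance Map (TFRIM), (2) classifies
spirometry-defined SAD with a dual-stream network calibrated by demographics,
and (3) validates every stage against a physics-based synthetic IOS simulator
with known ground truth, because the clinical cohort the method was developed
on is private.

## Synthetic recordings (the ground-truth oracle)

The simulator drives a single-compartment
resistance–inertance–compliance (RIC) model

    Z(f, t) = R(f, t) + j (2πf·I − 1/(2πf·C)),
    R(f, t) = (R0 + dR_exp·1[expiration]) − fdep·(f − 5),  floored at 0.05,

with a tidal flow sinusoid (default 12 breaths/min, 0.5 L/s amplitude;
expiration is the positive-flow half-cycle) and a 2.5 Hz pulse-train
excitation represented by its first 24 cosine harmonics with 1/m amplitude
decay (first-harmonic amplitude 0.3 L/s — device excitation content is not
public, so these are stipulated). Pressure is synthesised quasi-statically:
each harmonic is multiplied by the instantaneous |Z| and phase-shifted by
arg Z. This is valid because Z varies on the breathing timescale (~5 s),
an order of magnitude slower than the excitation period (0.4 s), and it keeps
the generating impedance available in closed form for every estimator test.
Additive white measurement noise defaults to 0.002 kPa (pressure) and
0.01 L/s (flow).

Group-conditional phenotypes are anchored to the published cohort statistics:
mean R at 5 Hz 0.47 (SAD) vs 0.37 (non-SAD) kPa/(L/s), X5 −0.16 vs −0.10,
resonant frequency 17.6 vs 13.6 Hz, FEF ratio means 0.43/0.49/0.35 vs
0.88/0.94/0.77. Inertance and compliance are obtained by inverting the
drawn (X5, Fres) pair through the RIC closed forms (e.g. non-SAD means give
C = 0.276 L/kPa, I = 4.95e-4 kPa·s²/L). The expiratory increment dR_exp
(0.15 vs 0.03 kPa/(L/s)) is the within-breath SAD signature; the frequency
slope fdep matches the published R5−R20 gap (~0.006 vs ~0.003 per Hz).

A latent severity z-score per subject couples waveforms to labels: it shifts
R0, dR_exp and fdep jointly, and each spirometry ratio is drawn as
mean − sd·(ρ·z + √(1−ρ²)·ε) with ρ = 0.9, truncated to (0.05, 2.0). The
marginals therefore keep the published means and (slightly shrunken)
standard deviations while higher-severity subjects get lower ratios. ρ = 0.9
makes the link strong but stochastic (label residual sd ≈ 0.44 of the
marginal sd); a majority-vote oracle that knew each subject's phenotype
exactly would reach ≈ 0.95 voted accuracy under these conditions, which is
the ceiling any classifier trained on this generator can approach.
Demographics are drawn group-conditionally from the published
age/height/weight statistics, and R0 is additionally scaled by a ±15 %
age/height factor, so demographics alone are only weakly predictive — by
design, mirroring the near-chance demographics-only ablation reported for
the clinical cohort.

What the simulator does *not* emulate: multi-compartment or nonlinear airway
mechanics, inspiratory/expiratory inertance asymmetry, device-specific pulse
shapes, upper-airway shunt, swallowing/cough artefacts, or realistic
non-white sensor noise. Passing tests on this generator demonstrates that
the pipeline recovers a known time-varying RIC impedance and learns a
planted, physiologically oriented group difference — not clinical
performance on real patients.

## TFRIM construction

The recording is cropped to its first 9120 samples (22.8 s; shorter records
are rejected, never padded) and sliced into 4-s Hamming windows hopped by
0.4 s → exactly 48 windows. Within each window the impedance is the ratio of
Welch-averaged cross- to auto-power densities, Z_t[k] = S_PF/S_FF, and the
magnitude-squared coherence γ²_t[k] = |S_PF|²/(S_PP·S_FF) gates quality:
entries below γ_th = 0.90 are zeroed, then the 24 frequency channels with
the highest time-mean coherence are kept (ties fall to the lower, more
physiologically informative frequency) and re-sorted ascending, giving a
(2 × 24 × 48) resistance/reactance tensor. Selection uses only the
recording's own signals — no dataset statistics, no labels.

Numerical choices, each forced by an oracle failure mode we measured:

- **Sub-segment length 0.8 s** (two excitation periods), half-overlapping →
  9 tapered sub-segments per window. Every harmonic then falls on an even
  sub-segment bin, where the periodic Hamming kernel has exact nulls, so
  inter-harmonic leakage in the Welch cross-spectra vanishes by
  construction. (Generic sub-segment lengths leave 2–3 % bias at weak
  harmonics.) Zero-padding the sub-segment FFTs to the window length keeps
  the 0.25 Hz grid of the 4-s window.
- **Zero-phase 1 Hz high-pass (Butterworth order 4, Gustafsson
  initialisation) on both channels.** An identical filter on pressure and
  flow cancels exactly in the impedance ratio and in the coherence, while
  removing the large breathing-band component whose leakage otherwise biases
  the low harmonics. Per-window detrending is *not* applied in this mode: a
  detrend projects the two channels differently and measurably breaks their
  exact linear relation (coherence dipped to 0.988 on noise-free input).
  With the high-pass, noise-free recordings give γ² ≥ 0.9999 and worst-case
  impedance error ≈ 0.2 % at every harmonic and window. Setting
  `highpass_hz = 0` restores linear detrending for non-oscillometric use.
- **Flow floor:** bins with S_FF below 1e−12 of the band maximum are flagged
  undefined instead of divided, so unexcited bins cannot produce spurious
  impedance.
- **Whole-recording impedance** (the classical single-spectrum estimate) is
  computed from linearly detrended, Hamming-tapered channels; the taper
  cancels in the ratio at excited bins. Scalar IOS indices (R5/R20/R35, X5,
  Z5, Fres) are interpolated after sampling the spectrum at the excitation
  harmonics only — interpolating over the full DFT grid lets leakage bins
  mirror the nearest harmonic and biases the resonant frequency by ~1 Hz,
  versus < 0.1 Hz with harmonic sampling.

## Dual-stream network

Implemented on a reverse-mode automatic-differentiation engine written in
numpy inside this package (`tfrim_sad.nn`); all custom gradients
(convolutions, the state-space scan) are validated against finite
differences in the test suite.

- **TFRIM branch:** a two-channel positional grid (normalised frequency and
  time coordinates) is concatenated to the map — absolute spectral position
  matters, unlike in natural images — then a 7×7 stem convolution, two
  multi-branch blocks (parallel 3×3-avg-pool+1×1, 3×1→1×3, 3×3 and 1×1
  paths, concatenated, plus a 1×1-projected external residual), a CBAM
  attention block (channel attention from pooled descriptors through a
  shared MLP, then 7×7 spatial attention), global average pooling, and a
  projection to 128 dimensions.
- **Temporal branch:** three strided convolutions (kernel 7 stride 2, then
  5/2 and 3/2) map the 2×9120 waveform pair to a 64-channel sequence of
  length 1140; a pre-norm selective state-space block with zero-order-hold
  discretisation (Ā = exp(ΔA), b̄ = (exp(ΔA)−I)A⁻¹b, with the analytic
  limit Δ·b as A→0; Δ, b, c generated from the current input, Δ through a
  softplus so the scan is unconditionally stable) plus residual, then
  learned softmax attention pooling over time and projection to 128-d.
- **Demographic calibration (DAFM):** the standardised (age, sex, height,
  weight) vector passes a three-hidden-layer MLP (32-64-64) to a 512-d
  output split into scale α and shift β (256 each); the fused 256-d feature
  (TFRIM first, then temporal) becomes α⊙x + β. The final layer is
  identity-initialised (α=1, β=0) so training starts from no modulation.
  Concatenation, gating and additive-bias fusion heads are available behind
  a config switch for comparison.
- **Head:** one shared MLP 256→64→3 produces three logits — one per FEF
  index, ordered (FEF25–75, FEF50, FEF75) — squashed by sigmoids.

Unspecified widths are the smallest consistent with the published
128/256/512 dimensions: stem 32, multi-branch path widths 32 then 64, CBAM
reduction 8, temporal D=64 with state size N=16, head hidden 64, dropout
0.3, A initialised diagonal negative-real (−1…−N per channel). A reduced
preset (`NetworkConfig.small()`: widths 8–16, feature dim 32, stride-4
front-end → sequence length 143) exists for desk-scale experiments; it is
the configuration used by the cross-validation acceptance check.

Any branch can be ablated; with demographics only, the demographic MLP feeds
the classifier directly.

## Labels, training and evaluation

Soft labels y_soft(k) = σ(20·(0.65 − v_k)) supervise a 3-way multi-label
binary cross-entropy (predictions clipped to [1e−7, 1−1e−7]). Hard
abnormality is strict (v_k < 0.65); the subject label needs ≥ 2 of 3. At
inference each head is binarised at τ = 0.5 — the ≥ side counts as abnormal,
a convention the original description leaves open — and the majority vote
decides SAD. The impairment index
S = y₁y₂ + y₂y₃ + y₁y₃ − 2y₁y₂y₃ is the multilinear extension of that vote
to the unit cube (S ∈ [0,1], permutation-symmetric, equal to the vote on
binary corners); it is reported for embedding analysis and never enters the
loss.

Training uses Adam (default lr 1e−4, batch 256 — the published protocol)
with cosine annealing and early stopping on a validation split carved out of
the training portion (default 10 %, stratified); held-out test folds never
steer stopping. Patience defaults to 10 epochs and the maximum to 200 —
the original protocol states only "stopped when validation loss no longer
decreased". Batch size is auto-reduced with a warning for cohorts smaller
than the batch. Z-score statistics are fitted per channel on the training
portion of each fold only, σ floored at 1e−8, and frozen before they touch
held-out subjects; a mutation test asserts the freeze. Cross-validation is
stratified by the hard label (switchable to pure random); metrics are
accuracy, sensitivity, specificity, precision and F1, per subtask (ground
truth: per-index hard abnormality) and for the voted main task, per fold and
averaged.

### Desk-scale study sizes

The published protocol ran on 2510 subjects with a GPU. The package's
acceptance experiment uses the sizes a desk machine can handle: a
200-subject synthetic cohort (42 % SAD phenotypes), 2-fold cross-validation,
the reduced network preset, and a correspondingly scaled optimisation
(lr 1e−3, batch 16, ≤ 150 epochs, patience 30, 15 % validation split) — at
~100 training subjects per fold, the published lr of 1e−4 with batch 256
yields too few update steps to converge. The demographics-only ablation runs
under identical settings and stays near chance, qualitatively mirroring the
published ablation ordering.

## Known limitations

- The network is numpy-based and CPU-bound; the full-width configuration is
  practical for inference and small studies, not for 2510-subject training.
- The simulator's quasi-static pressure synthesis makes the within-breath
  resistance switch piecewise-constant; real airway mechanics are smoother
  and nonlinear.
- EDF input/output is not implemented; recordings are CSV (the format is
  documented in `docs/formats.md`).
- Subtask metrics use hard abnormality as ground truth; the original report
  is ambiguous between soft- and hard-label ground truth for those tables.
- With a 4-s analysis window and ~5-s breaths, each window mixes inspiration
  and expiration; the within-breath resistance contrast is attenuated but
  its direction is preserved (asserted over a 20-seed majority test).
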