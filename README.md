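# tfrim-sad

Within-breath impulse-oscillometry (IOS) analysis for small airway
dysfunction (SAD): time–frequency respiratory impedance maps, a dual-stream
classifier with demographic calibration, and a physics-based synthetic IOS
simulator that provides ground truth for every stage.

## The problem

Spirometry defines SAD from forced-expiratory flow ratios: with
v_k = measured/predicted for FEF25–75, FEF50 and FEF75, an index is abnormal
when v_k < 0.65 and a subject is SAD when at least two of three are
abnormal. Forced manoeuvres are effort-dependent and hard for many
patients. IOS needs only tidal breathing: a weak multi-frequency pressure
pulse train (2.5 Hz fundamental) is applied at the mouth and the respiratory
impedance Z(f) = R(f) + jX(f) is estimated from the pressure/flow ratio.
Classical IOS analysis averages whole recordings into scalars (R5, X5,
Fres, …), discarding the within-breath dynamics — expiratory resistance
elevation in particular — that carry much of the SAD signature.

## The method

1. **TFRIM.** The two-channel recording (400 Hz, 9120 samples) is sliced
   into 4-s Hamming windows hopped by 0.4 s (48 windows). Per window,
   impedance is the Welch cross-spectral estimate Z_t[k] = S_PF/S_FF, and
   the coherence γ²_t[k] = |S_PF|²/(S_PP·S_FF) gates quality: entries below
   γ_th = 0.90 are zeroed and the 24 highest-coherence frequency channels
   are retained, giving a 2×24×48 resistance/reactance map.
2. **Dual-stream network.** A CNN branch (positional encoding, multi-branch
   inception-style blocks, CBAM attention) encodes the TFRIM to 128-d; a
   temporal branch (strided conv front-end, selective state-space scan with
   zero-order-hold discretisation Ā = exp(ΔA), attention pooling) encodes
   the raw waveforms to 128-d. The concatenated 256-d feature is calibrated
   per subject by an affine (α, β) generated from standardised
   age/sex/height/weight (DAFM: x_mod = α⊙x_fused + β).
3. **Soft-label multi-task training and voting.** Three sigmoid heads
   predict the abnormality of the three FEF indices, trained against soft
   labels y_soft(k) = σ(20·(0.65 − v_k)) with mean binary cross-entropy;
   at inference the heads are binarised at 0.5 and majority-voted into the
   SAD decision. The impairment index
   S = y₁y₂ + y₂y₃ + y₁y₃ − 2y₁y₂y₃ summarises the three soft labels
   (it equals the majority vote on binary inputs).

Because the clinical cohort is private, the package ships a simulator that
generates IOS cohorts from a known time-varying
resistance–inertance–compliance model with published-cohort-anchored group
statistics; every estimator is tested against its closed form. See
`docs/methods.md` for the model and all numerical choices.

## Worked example

```sh
tfrim-sad simulate --n 20 --sad-fraction 0.4 --seed 1 --out cohort/
tfrim-sad build --manifest cohort/manifest.csv --out cohort/maps.h5
tfrim-sad train --manifest cohort/manifest.csv --out run/ --folds 2 --seed 1 \
    --max-epochs 10 --batch-size 16 --lr 1e-3
```

The train command prints the cross-validated voted metrics, e.g. (20-subject
smoke cohort, 10 epochs):

```json
{
  "accuracy": 0.7424242424242424,
  "f1": 0.8012820512820513,
  "precision": 0.7291666666666667,
  "sensitivity": 0.9166666666666667,
  "specificity": 0.525
}
```

Accuracy is the fraction of subjects whose voted SAD decision matches the
spirometry-derived hard label; sensitivity/specificity are with SAD as the
positive class. (A 20-subject run is a smoke test; the package's acceptance
experiment uses 200 subjects, where the voted accuracy is far from chance —
see below.)

Predict on one recording from a trained fold checkpoint:

```sh
tfrim-sad predict --recording cohort/S0003.csv \
    --checkpoint run/checkpoint_fold0.npz \
    --age 55 --sex 1 --height 170 --weight 78
```

prints the three head probabilities, their votes, the SAD decision and the
impairment index S.

From Python, the same pipeline is available as scikit-learn style
estimators:

```python
from tfrim_sad import (generate_cohort, cohort_to_arrays,
                       DualStreamSADClassifier, NetworkConfig)

records, recordings, _ = generate_cohort(n=40, seed=1)
data = cohort_to_arrays(records, recordings)
clf = DualStreamSADClassifier(network=NetworkConfig.small(),
                              lr=1e-3, batch_size=16, max_epochs=10)
clf.fit({k: data[k] for k in ("tfrim", "wave", "demo")}, data["y_soft"])
probs = clf.predict_proba({k: data[k] for k in ("tfrim", "wave", "demo")})
```

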