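# File formats

## Recording CSV

One file per subject. Two `#`-prefixed metadata lines, then a two-column
CSV body; samples are stored at float32 precision.

```
# fs_hz=400
# subject_id=S0042
pressure_kpa,flow_lps
-0.012345,0.23456
...
```

| field | type | units | notes |
|---|---|---|---|
| `fs_hz` | float | Hz | required; parse fails without it |
| `subject_id` | string | — | optional, defaults to empty |
| `pressure_kpa` | float32 | kPa | oral pressure |
| `flow_lps` | float32 | L/s | airflow; expiration positive |

Non-finite samples, ragged rows or extra columns are parse errors naming the
expected schema.

## Manifest CSV

One row per subject; `subject_id` must be unique (duplicates are rejected —
one eligible record per subject).

```
subject_id,age_years,sex,height_cm,weight_kg,fef2575_ratio,fef50_ratio,fef75_ratio,recording_path
```

`sex` parses from `{M,F}` or `{1,0}` (male = 1). The three `*_ratio` columns
are measured/predicted FEF ratios and must be positive; `recording_path` is
relative to the manifest's directory.

## TFRIM HDF5 container

| dataset / attr | shape | dtype | meaning |
|---|---|---|---|
| `/tfrim` | (n, 2, 24, 48) | float32 | channel 0 = resistance, 1 = reactance, kPa/(L/s) |
| `/freqs_hz` | (n, 24) | float64 | retained frequencies per subject, ascending |
| `/times_s` | (48,) | float64 | window centres |
| `/mean_coherence` | (n, 24) | float64 | time-mean coherence per retained channel |
| `/subject_ids` | (n,) | bytes | subject identifiers |
| attrs | — | — | `fs_hz`, `gamma_th`, `window_s`, `hop_s` |

## Configuration YAML

Nested blocks mirroring `tfrim_sad.io.PipelineConfig`: `fs_hz`,
`duration_s`, `sad_fraction`, `breathing`, `excitation_harmonics`, `tfrim`
(`window_s`, `hop_s`, `gamma_th`, `n_channels`, `subsegment_s`,
`subsegment_overlap`, `highpass_hz`), `labels` (`vth`, `lam`, `tau`),
`training` (`lr`, `batch_size`, `max_epochs`, `patience`, `val_fraction`,
`seed`), `folds`. Load→dump→load is byte-idempotent; values are validated on
load.

## Reports

`metrics.json` holds the averaged and per-fold metric dicts (accuracy,
sensitivity, specificity, precision, f1). `history_fold<k>.csv` has columns
`epoch,train_loss,val_loss,lr`. Every CLI run writes `run_manifest.json`
with the stage name, seed, config hash and package version.
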