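# setupcorr

Off-line six-degree-of-freedom (6DoF) setup-error correction protocols for
image-guided radiotherapy, with the population statistics and synthetic
cohort simulation needed to evaluate them.

The package implements the correction policies **NAL** (negated mean of the
first three measured fractions), **eNAL** (NAL plus weekly follow-up
measurements feeding a running linear least-squares trend fit,
`C_k = -(S_k + a_k * f_k)`), the hybrid **eNAL++** (eNAL in which every
imaged fraction is corrected online instead of off-line), and the
`none` / daily-`online` baselines. Residual courses are decomposed per axis
into the population mean `mu`, the systematic SD `Sigma` (SD over patients
of per-patient means) and the random SD `sigma` (RMS of per-patient SDs),
and protocols are compared against their imaging workload (CBCT count).

Conventions: translations in mm, rotations in degrees; pitch/roll/yaw are
rotations about the x/y/z axes (IEC 61217); a correction is the vector added
to the raw error, so `residual = error + correction`; rotational corrections
are clipped to the +/- 3 deg couch limit; fractions are 1-based.

## Layout

| module | contents |
| --- | --- |
| `setupcorr.core` | `SetupError6DoF`, `TreatmentCourse`, `Point3D`, rotation matrices, off-isocenter displacement |
| `setupcorr.protocols` | `CorrectionPolicy`, imaging schedules, NAL mean, running LSQ fit, `apply_policy`, workload |
| `setupcorr.stats` | `decompose` (mu / Sigma / sigma), `compare_protocols` |
| `setupcorr.simulate` | `SimulationConfig`, `simulate_population` (truncated-normal cohort generator) |
| `setupcorr.io` | match-table CSV reader/writer, residual dumps |
| `setupcorr.cli` | `setupcorr` command-line interface |

## CLI

All randomness flows from one seed (config key `seed`, overridable with
`--seed`; flags win over config values).

```sh
# generate a synthetic cohort as a match-table CSV
setupcorr simulate --n-patients 19 --n-fractions 30 --seed 1 -o cohort.csv

# decompose raw errors into mu / Sigma / sigma per axis
setupcorr stats -i cohort.csv -o stats.csv

# apply one protocol; dump per-fraction residuals, flags and corrections
setupcorr run -i cohort.csv -p enal_pp --seed 1 -o residuals.csv

# full comparison: summary.csv, residuals.csv, run.json (+ --plot)
setupcorr compare -i cohort.csv --seed 1 --out-dir results/ --plot
```

`compare` also accepts a YAML config instead of an input table:

```yaml
seed: 1
simulation: {n_patients: 19, n_fractions: 30}
policies: [none, nal, enal, enal_pp, online]
online_sd: 0.2           # SD of the residual left by an online correction
policy_params: {nal_length: 3, followup_start: 8, followup_interval: 5}
```

Match-table CSV layout (units fixed, header required):

```
patient_id,fraction,timepoint,tx_mm,ty_mm,tz_mm,pitch_deg,roll_deg,yaw_deg
```

with `timepoint` one of `post_setup`, `post_correction`, `post_treatment`;
treatment courses are built from the `post_setup` rows.

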