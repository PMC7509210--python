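# steerlimb

Direction-resolved analysis of upper-limb surface-EMG and steering torque
recorded during steering tasks. Given per-trial multichannel time series
(10 EMG channels, steering torque in N·m, steering angle in degrees), the
package computes:

- **EMG–torque correlations** per muscle and steering direction
  (clockwise/counterclockwise), defined as the peak of the normalized
  cross-correlation over a bounded lag window, with a strict > 0.75
  "strong" classification;
- **amplitude statistics** (mean normalized activation envelope per
  direction) and **contribution ratios** `c_i = r_i·a_i / Σ r_j·a_j`
  ranking muscle importance per direction;
- **EMG-to-torque time delays** as the lag of maximum absolute
  cross-correlation (negative = muscle activity precedes torque);
- **steering-smoothness metrics** of the torque signal: approximate
  entropy (Pincus, self-matches included, SD-relative tolerance) and the
  mean sliding-window standard deviation (SSD);
- **cohort aggregation** (mean ± SD, median, quartiles) plus paired
  sign-flip permutation tests for direction dependence (raw and
  Holm-adjusted p-values).

Because no public dataset exists for this paradigm, the package ships a
first-class **synthetic cohort generator**: torque-coupled EMG envelopes
with per-muscle direction-dependent gains and lead times (0–500 ms),
modulating band-limited (20–450 Hz) Gaussian carriers, for both active
(target-following) and passive (disturbance-rejection) tasks and all
hand-position/arm-mode conditions. Every generated cohort comes with a
ground-truth parameter table, so all downstream stages have recovery
tests.

## File formats

- Trial data: CSV with header `time,torque,angle,emg_01..emg_10`
  (UTF-8, comma-delimited, `.` decimal), one row per sample.
- Trial metadata: JSON sidecar `<basename>.meta.json` with
  `subject_id`, `arm_mode` (`both`|`single`), `hand_position`
  (`0300`,`1010`,`1200` for both-arm; `0300`,`0130`,`1200` for
  single-arm), `task` (`active`|`passive`).
- Positive torque = clockwise steering effort (recorded in metadata).
- Result tables: CSV with a `# schema=steerlimb.v1 kind=...` header line.

## CLI

```sh
# generate a synthetic cohort (trial CSVs + meta JSONs + ground_truth.csv)
steerlimb simulate --config sim.yaml --out cohort/ --seed 7

# envelopes + direction segments for one trial
steerlimb preprocess --trial cohort/S01.csv --out pp/

# per-trial analyses
steerlimb analyze correlations --trial cohort/S01.csv --out s01_results.csv
steerlimb analyze delays       --trial cohort/S01.csv --out s01_delays.csv
steerlimb analyze smoothness   --trial cohort/S01.csv --out s01_smoothness.csv

# full cohort pipeline: per-subject results, cohort_summary.csv,
# direction_tests.csv, manifest.json
steerlimb report --in cohort/ --out results/ --seed 1
```

`sim.yaml` holds `SimulationConfig` fields, e.g.

```yaml
n_subjects: 20
duration_s: 60.0
fs: 1000.0
task: active
arm_mode: both
hand_position: "0300"
seed: 7
```

## Notes on method choices

- All envelope filtering is zero-phase, so the preprocessing adds no lag
  that would bias the delay estimates.
- Direction labeling uses a torque dead-band (default 5 % of trial max
  |torque|) with a minimum episode duration (default 0.5 s).
- Correlations are computed on concatenated per-direction episodes with
  per-segment mean removal; delays on the contiguous labeled span with
  both directions pooled.
- Analyses run on envelopes/torque decimated to 100 Hz (configurable):
  envelopes are band-limited to 6 Hz, and kHz-rate samples would make
  approximate entropy degenerate.
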