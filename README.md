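# saccadetools

Simulation and analysis pipeline for overlap pro/antisaccade eye-movement
tasks in a three-group pediatric cohort design (healthy controls, medicated
chronic epilepsy, unmedicated controlled epilepsy).

The pipeline covers:

- **`synthetic_cohort`** — cohort generator: children with clinical
  covariates, trial-level saccade events or raw 1000-Hz gaze traces.
  Latencies come from a promptness (1/SRT) race between a main unit
  N(mu, sigma²) and a zero-mean early unit N(0, sigma_e²); kinematics
  follow a linear amplitude/peak-velocity main sequence; antisaccade
  direction errors have a latency-dependent (logistic) probability, with
  configurable correction probability and delay.
- **`event_processing`** — gaze CSV / ASC-like readers, velocity-based
  saccade detection (Savitzky–Golay derivative, hysteresis bounds), blink
  handling, and the trial-validity gate (central fixation at target onset,
  no blinks in the response window).
- **`trial_classification`** — first-valid-saccade rule (SRT 80–1000 ms,
  amplitude ≥ 1°), correct/error labelling per task, express flag
  (SRT 80–120 ms on correct prosaccades), and correction detection for
  antisaccade direction errors (opposite saccade < 300 ms after error
  offset).
- **`saccade_metrics`** — reciprocal SRT, gain, peak velocity, per-child
  main-sequence regression evaluated at 8°, and per-child proportion
  measures (error rate, corrected rate, express rate).
- **`later_model`** — recinormal latency model with optional early unit:
  race CDF, exact one-sample Kolmogorov–Smirnov statistic, KS-minimisation
  fitting (grid + Nelder–Mead), and reciprobit coordinates.
- **`group_stats`** — trial-level random-intercept mixed models, child-level
  GLMs for proportion outcomes with Bonferroni pairwise contrasts, age
  curve estimation (quadratic vertex), forward-stepwise clinical factors,
  Spearman rho and R² change.
- **`cli_reporting` / `cli`** — stage orchestration with manifests and a
  `saccadetools` command-line entry point.

## Command line

```sh
# full pipeline on a synthetic cohort
saccadetools all --outdir out --seed 1

# with a YAML config (flags override config keys)
saccadetools all --config run.yaml --outdir out --seed 1

# individual stages (prerequisites run automatically unless --no-deps)
saccadetools simulate --outdir out --seed 1
saccadetools report --outdir out --seed 1
```

Example `run.yaml`:

```yaml
seed: 1
sim_mode: events        # or "samples" for raw gaze traces + detection
sim:
  n_per_group: [48, 15, 11]
  trials_per_task: 30
  blink_rate: 0.05
```

Each run writes CSV outputs per stage (`children.csv`, `trials.csv`,
`events*.csv`, `labels.csv`, `measures.csv`, `later_fits.csv`,
`reciprobit.csv`, `stats_*.csv`, `summary_by_group.csv`,
`es_error_scatter.csv`) plus `manifest.json` recording the seed and a
config hash; a fixed seed reproduces every output byte-for-byte.

External data can be ingested instead of simulated: gaze samples as CSV
(`trial_id,t_ms,x_deg,y_deg,valid_flag` with a trial-metadata CSV) or an
ASC-like text dialect (`MSG <t> TRIALID <id> <task> <child>`,
`MSG <t> TARGET_ON <side>`, `SBLINK`/`EBLINK`, and `<t> <x> <y>` sample
lines), or pre-detected event tables
(`saccadetools.event_processing.read_event_tables`).

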