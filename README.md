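# trialhist

Analysis toolkit for two-alternative odor-cued spatial-choice experiments in
which behavior and single-unit activity depend on recent trial history.
Everything is exercisable on synthetic sessions with known ground truth, so
each stage is testable without external recordings.

Components:

- **`trialhist.synthetic`** — generator for task-event streams,
  history-dependent choices (extended logistic model), outcomes,
  inhomogeneous-Poisson spike trains with event-locked modulations,
  saline/muscimol session sets, and latent-coupled units.
- **`trialhist.behavior`** — design-matrix construction under the trial
  inclusion/coding rules, logistic model fitting (IRLS, Wald CIs, separation
  diagnostics), cross-validated simulated-choice model comparison,
  inactivation-session fits, movement metrics, conditional psychometrics.
- **`trialhist.preference`** — per-trial epoch firing rates, ROC-based
  preference index `2*(ROC_area - 0.5)` with Monte-Carlo permutation
  significance, population summaries, port-vs-movement-direction
  disambiguation, Gaussian-smoothed PSTHs.
- **`trialhist.sliding`** — sliding-window (100 ms bins every 10 ms) OLS
  regression of firing rate on previous/current choice and outcome, per-bin
  95% CIs and significance, population time courses.
- **`trialhist.choicelink`** — trial-by-trial linkage between normalized
  pre-stimulus rate and choosing a unit's preferred port on ambiguous
  trials, with permutation-tested slopes (line or logistic).
- **`trialhist.io` / `trialhist.config` / `trialhist.cli`** — CSV readers
  and writers, validated YAML run configuration, and the umbrella CLI.

## CLI

All stages are exposed through one entry point:

```sh
trialhist simulate -c config.yaml -o outdir           # synthetic cohort
trialhist behavior fit --trials trials.csv --model extended1 -o fits.csv
trialhist behavior compare --trials trials.csv --seed 1 -o cv.csv
trialhist behavior inactivation --trials set.csv -o inact.csv
trialhist preference --trials trials.csv --spikes spikes.csv \
    --units units.csv --variable choice --lag 1 --seed 1 -o pref.csv
trialhist sliding --trials trials.csv --spikes spikes.csv --units units.csv \
    --align valve_open -o sliding.csv
trialhist link --trials trials.csv --spikes spikes.csv --units units.csv \
    --preference-table pref.csv --seed 1 -o slopes.csv
trialhist run -c config.yaml -o outdir                # full pipeline
```

A packaged demo configuration (`src/trialhist/data/demo.yaml`) runs the full
pipeline end-to-end in well under a minute and is bit-reproducible under a
fixed seed. Configurations must set an explicit `seed`; unknown keys are
rejected.

### File formats

Trial tables and spike trains are plain CSV. Trials carry one row per trial
(event times in seconds from session start, odor left-fraction, choice
`L`/`R`/`none`, rewarded `0`/`1`/`none`, condition
`saline`/`muscimol`/`baseline`). Spikes are one row per spike
(`unit_id, spike_time_s`) with a companion units file
(`unit_id, mouse_id, session_id, recorded_side`) so silent units round-trip.

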