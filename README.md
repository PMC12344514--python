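# connsim

Group-to-individual similarity of resting-state functional connectivity, as a
tested, reusable pipeline:

- **`connsim.synthetic_data`** — synthetic multi-subject cohorts drawn from
  block-structured network covariance with a tunable heterogeneity knob
  (eta in [0, 1]), motion-like framewise-displacement traces, and behavioral
  outcomes whose predictability attenuates with decreasing group similarity.
- **`connsim.connectivity`** — frame censoring and run concatenation,
  temporal-SNR ROI exclusion, Pearson/Fisher-z edge vectors over a canonical
  edge enumeration, top-fraction inter-individual-variance feature selection,
  within/between-network aggregation, and training-set group models.
- **`connsim.similarity`** — ICC(A,1) (two-way random effects, absolute
  agreement, single-rater units) between the group model and each individual,
  benchmark classification (poor/moderate/good/excellent), and a permutation
  null that shuffles ROI-to-network assignments.
- **`connsim.prediction`** — elastic-net outcome prediction with 10-fold
  cross-validation over a mixing/penalty grid, selected by minimum mean CV
  error; degenerate (zero-feature) models are flagged and report r = 0.
- **`connsim.moderation`** — OLS moderation of predictive performance by
  similarity (observed ~ predicted × ICC), Johnson–Neyman regions of
  significance, and single-covariate screens of ICC.
- **`connsim.cli`** — end-to-end orchestration with YAML configs, one master
  seed, and a machine-readable JSON report.

## Command-line usage

```sh
# write a synthetic cohort (per-subject TSV series + FD, outcomes CSV, truth JSON)
connsim simulate --seed 1 --out scratch/cohort

# full pipeline on the default synthetic config
connsim run --seed 1 --out scratch/run

# individual stages
connsim icc --seed 1 --out scratch/icc        # similarity only
connsim null --seed 1 --out scratch/null      # + permutation null
connsim predict --seed 1 --out scratch/pred   # + elastic nets
connsim moderate --seed 1 --out scratch/mod   # + moderation / JN / covariates

# check a config without running
connsim validate --config config.yaml
```

All stage parameters (censoring threshold, minimum low-motion minutes, tSnR
SD cutoff, variance fraction, CV folds, permutation count, alphas, seeds) live
in one YAML config; see `connsim.cli.RunConfig` for keys and defaults. In
`files` mode the config points at a parcellation TSV, per-subject series/FD
TSVs and an outcomes CSV instead of simulating.

Outputs per run: `similarity.csv`, `features.csv`, `group_model.csv`,
`null.csv`, `scores.csv`, `moderation.csv`, `covariate_screen.csv`, and
`report.json` (full machine-readable summary).

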