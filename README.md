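# minddiet

Toolkit for MIND-style dietary index scoring and its validation against mild
cognitive impairment (MCI) in older-adult cohorts. It packages:

- **`minddiet.scoring`** — banded 0 / 0.5 / 1 scoring of food-group intake
  frequencies. Two rule tables ship as data: the 11-component Malaysian
  adaptation **MY-MINDD** (7 brain-healthy + 4 unhealthy groups, maximum 11
  points) and the 15-component original **MIND** index (including olive oil,
  wine, and cheese, maximum 15 points). Intakes in mixed units (per day /
  week / month) are normalised to servings per week before band lookup;
  custom rule tables load from YAML and are validated for gap-free,
  overlap-free band partitions.
- **`minddiet.cognition`** — Petersen-style MCI classification (subjective
  memory complaint, RAVLT ≥ 1.5 SD below a reference mean, intact IADL,
  preserved global function, no dementia) plus BMI categorisation.
- **`minddiet.cohort`** — a deterministic synthetic-cohort generator
  calibrated to printed cohort marginals (n = 810 default): truncated-normal
  covariates with exact-mean calibration, moment-matched log-normal income,
  gamma intake distributions solved so expected component scores hit their
  target means, a logistic outcome model parameterised by odds ratios with a
  numerically solved intercept (30.2% default prevalence), and
  status-conditional neuropsych batteries. Every variable draws from its own
  counter-based random stream, so results are a pure function of
  (config, seed) and appending rows never perturbs earlier rows.
- **`minddiet.analysis`** — quantile score groups with ties-to-lower,
  descriptive tables, one-way ANOVA / Mann–Whitney / chi-square contrasts,
  Pearson correlations, per-component MCI contrasts, Kolmogorov–Smirnov
  normality checks, missing-data handling (complete-case, mean/mode fill,
  Gaussian chained-equations multiple imputation with Rubin pooling), and a
  three-block hierarchical logistic regression with Wald CIs fitted on a
  common complete-case subsample.
- **`minddiet.io` / `minddiet.cli`** — CSV schemas and the `minddiet`
  command-line interface.

## CLI

```sh
minddiet simulate --seed 1 --n 810 --out cohort.csv      # synthetic cohort
minddiet score    --cohort cohort.csv --out scores.csv   # MY-MINDD scoring
minddiet score    --cohort cohort.csv --scoring-table MIND-original --out s15.csv
minddiet classify --cohort cohort.csv --out classified.csv
minddiet analyze  --cohort classified.csv --out report/ --outcome true_mci
minddiet report   --report-dir report/
```

`analyze` writes four report tables (`by_score_group.csv`, `by_outcome.csv`,
`logistic_models.csv`, `component_comparison.csv`), a machine-readable
`stats.json`, and a `run.log` with seeds and row counts. `--scoring-table`
accepts a builtin name or a path to a custom YAML rule table;
`--k-groups`, `--imputation`, and `--criteria` expose the remaining knobs.

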