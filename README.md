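# bscore

Dataset-adjusted (relative) performance of blood-pressure estimation
systems.

Absolute error metrics (RMSE, MAE, ...) for cuffless BP estimation depend
as much on the dataset as on the model: a resting laboratory cohort of
young, healthy subjects is far "easier" than 24-hour ambulatory recordings
of heterogeneous clinical patients. The **B-Score** makes performances
comparable across datasets by setting a model's test error against three
base performances of the dataset it was evaluated on:

- **B1-RMSE** — *inter*personal variability: the RMSE of the cohort mean
  used as a predictor (the population standard deviation of the reference
  values);
- **B2-RMSE** — *intra*personal variability: the RMSE of each subject's
  first ("calibration") measurement used as a persistent predictor;
- **M-RMSE** — the out-of-fold error of a fixed, deliberately minimalistic
  five-layer neural network (dropout + L2) trained on covariates every BP
  dataset has: age, sex, time of measurement, heart rate, the calibration
  BP with its time and heart rate, and the cohort mean.

With a model's test error T-RMSE (all four in mmHg):

```
B-Score = log10( sqrt( (B1·M / T²) · (B2·M / T²) ) )
```

Higher is better; the formula is scale-invariant, so the score is
dimensionless and directly comparable across datasets. The score is
defined only while T is smaller than every base performance; otherwise the
canonical report is the literal `B-Score < 0.00`. Scores are reported with
two decimals, systolic and diastolic always as two independent runs.
Transposing the formula gives the *coequal* T-RMSE — the error a model
would need on dataset B to match a score achieved on dataset A.

The package provides the metric layer, the minimal baseline with
subject-level k-fold evaluation and a size-dependent repeat schedule, a
generator of generic BP cohorts with controllable inter-/intrapersonal
variability and circadian rhythm, CSV/YAML/JSON plumbing, and a CLI.

## Worked example

The published "dobutamine" validation study (12 patients, 107 intraarterial
measurements, a pulse-wave-velocity device) printed these RMSEs:

```pycon
>>> from bscore import b_score, coequal_t_rmse
>>> sys = b_score(b1=32.25, b2=28.71, m=26.83, t=9.64)
>>> sys.value, sys.formatted
(0.9437480606001736, '0.94')
>>> b_score(b1=8.98, b2=7.86, m=7.95, t=10.35).formatted
'B-Score < 0.00'
```

Systolically the device beats every base performance comfortably
(score 0.94); diastolically its error 10.35 mmHg exceeds the minimal
baseline's 7.95 mmHg, so the score is below zero — a contrast invisible in
the absolute errors alone (9.64 vs 10.35). To match that systolic
performance on the much lower-variability MIMIC IV dataset
(B1 = 22.96, B2 = 21.97, M = 19.07):

```pycon
>>> coequal_t_rmse(22.96, 21.97, 19.07, sys.value).t
6.9823530024028235
```

i.e. a new model needs a systolic T-RMSE of 6.98 mmHg on MIMIC IV to be
coequal.

From the shell:

```sh
bscore score --b1 32.25 --b2 28.71 --m 26.83 --t 9.64      # -> 0.94
bscore coequal --b1 22.96 --b2 21.97 --m 19.07 --score 0.9437
bscore simulate --profile hard24 --seed 0 --out hard24.csv
bscore compute --data hard24.csv --seed 0 --out report.json
bscore clean --data raw.csv --channel systolic --out clean.csv
```

`bscore compute` validates the dataset (≥ 3 subjects × ≥ 3 measurements,
warning under 100 rows), optionally applies a single-pass 3-standard-
deviation outlier filter, computes B1/B2 and trains the minimal baseline
for M (subject-level 5-fold evaluation, repeated and averaged according to
dataset size), and writes a JSON report embedding the seed, schedule and
config needed to re-run bit-identically.

## Library surface

`MinimalBPRegressor` is a scikit-learn estimator (`fit`/`predict`,
`get_params`, pipeline-compatible); `m_rmse(dataset, config, seed)` wraps
the repeated subject-level cross-validation. `builtin_profiles()` /
`generate_dataset(profile, seed)` / `sd_sweep(...)` produce the generic
`lab`, `normal24` and `hard24` cohorts (10,000 subjects × 50 measurements)
used to exercise the metric's properties.

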