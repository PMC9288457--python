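# Methods

## The metric

For a dataset of n reference BP values y with subject grouping, all in
mmHg and per channel (systolic and diastolic are always two independent
runs):

- `B1 = sqrt(mean((y - mean(y))^2))` — the RMSE of the cohort mean as a
  predictor. This is the population (1/n) standard deviation, i.e.
  `sqrt((n-1)/n)` times the sample SD.
- `B2 = sqrt(mean((cal(y) - y)^2))` where `cal(y)` is the subject's first
  measurement in time order. The calibration rows themselves are included
  (their error is zero), which keeps n identical across B1/B2/M/T.
- `M` — out-of-fold RMSE of the minimal baseline (below).
- `T` — the evaluated model's RMSE against the same references.

`B-Score = 0.5·(log10 B1 + log10 B2) + log10 M − 2·log10 T`, algebraically
identical to `log10(sqrt((B1·M/T²)·(B2·M/T²)))` but stable for extreme
ratios. The score is defined only when `T < min(B1, B2, M)`; at equality
or above, the canonical report is the literal `B-Score < 0.00` (the
conservative reading of the defined-range rule). Display rounding is
half-up at two decimals; full precision is kept internally. The inverse
(`coequal_t_rmse`) is `T = 10^((0.5·(log10 B1 + log10 B2) + log10 M − S)/2)`
for a target score S and carries an attainability flag when the required T
is not below every base performance.

Degenerate inputs: any zero among B1/B2/M/T is a domain error (the log is
undefined); negative inputs are rejected. Ties in measurement time are
broken by stable input order, so a duplicated first timestamp yields a
deterministic calibration value.

Validity rules: scores require at least 3 subjects with at least 3
measurements each (hard failure listing offenders); fewer than 100 total
measurements adds a reliability warning. Rows violating `sbp > dbp > 0`
are flagged in the validation report but never silently dropped.

## The minimal baseline (M-RMSE)

The baseline measures how easy a dataset is to predict from universally
available covariates; it is an evaluation instrument, not a product, and
its weights are never persisted. Features per measurement row: age
(years), sex (0 = female, 1 = male; unknown values are an error, never
imputed), time of day as a sin/cos pair on the unit circle, minutes
elapsed since the subject's calibration measurement, heart rate, the
calibration BP, the calibration time of day (sin/cos), the calibration
heart rate, and the cohort mean. Features and targets are standardised
with statistics of the training fold only.

Architecture: input → dense 64 → 64 → 32 → 16 → linear output (five
layers), ReLU activations, inverted dropout 0.2 after each hidden layer,
L2 penalty 1e-3 on all weights, Adam (lr 1e-3), batches of 256, up to 200
epochs with patience-20 early stopping on a 10% inner validation split
(best-validation weights restored). A non-finite training loss triggers
one re-initialised retry, then a hard error. All of this is configurable
(`MinimalModelConfig`; YAML block `minimal_model:`).

Evaluation: subjects — never rows — are shuffled into k = 5 folds, so a
subject's calibration-adjacent values can never leak into the training
folds of its own predictions; every row receives exactly one out-of-fold
prediction per repeat. The procedure is repeated with reshuffled folds and
averaged on a size-dependent schedule: 10 repeats below 5,000 rows, 3 up
to 500,000, 1 above. One master seed fans out to per-repeat and per-fold
streams via `numpy.random.SeedSequence` counters; identical
(dataset, config, seed) gives bit-identical results.

Because dropout and L2 deliberately bias the network toward conservative
predictions, M can exceed B1 or B2 on easy datasets. On a noiseless
dataset where BP equals the calibration value exactly, the unregularised
network recovers the predictor to under 1 mmHg, while the default dropout
leaves a shrinkage floor of roughly 2–3 mmHg against a 10 mmHg
interpersonal spread — the intended price of generalised behaviour.

## The synthetic cohorts

`generate_dataset` simulates, per subject: a normal baseline
(inter-subject SD `inter_sd`), a circadian cosine with truncated-normal
amplitude and normally jittered phase whose minimum (nocturnal dip) sits
at 03:00, white within-subject noise (`intra_sd`), measurement times
uniform over the profile duration, heart rate with its own baseline and a
linear coupling (0.2 bpm/mmHg) to the BP excursion, uniform ages and
Bernoulli sex. Diastolic values reuse the systolic components scaled by
0.6 and are clipped strictly below systolic. Short-period
(Traube-Hering-Mayer, ~10 s) oscillations are statistically
indistinguishable from white noise at 50 samples per day and are folded
into `intra_sd`.

Built-in profiles (10,000 subjects × 50 measurements; means 120/75 mmHg):

| profile  | duration | inter_sd | intra_sd | circadian amplitude (mean ± sd) |
|----------|---------:|---------:|---------:|--------------------------------:|
| lab      |   30 min |        8 |        3 | 0 |
| normal24 |     24 h |       12 |        7 | 10 ± 3.3 |
| hard24   |     24 h |       18 |       12 | 15 ± 5 |

These parameters are configuration, not ground truth: they are chosen so
that variability is strictly ordered lab < normal24 < hard24, marginals
are unimodal and near-normal (|skew| and |excess kurtosis| < 0.1 at full
n), and a fixed fictional T-RMSE of 4 mmHg ranks the three families by
score. `sd_sweep` rescales the inter/intra/circadian SDs by a common
factor to hit a sequence of target total SDs (default 50,000 rows per
point), keeping the variability proportions fixed.

What the generator does **not** emulate: beat-level waveforms, measurement
device artefacts, drug responses, activity-driven BP surges, missing-data
patterns, or non-normal clinical tails. Passing tests on these cohorts
show the metric's algebraic and ordering properties under controlled
variability, not model performance on real recordings — which is why the
published real-dataset base performances enter the tests only as fixed
inputs.

## Cleaning

The 3-SD filter removes rows whose channel value lies outside
mean ± 3 sample SDs, with the moments computed once on the input (single
pass, no iterative re-trimming), per channel independently. Under
normality this keeps ≈ 99.73% of rows. Zero variance is a no-op with a
warning; missing required fields are dropped and counted at read time,
never imputed.

## Problem sizes in the test suite

The ordering checks train the baseline at 2,000 subjects × 50 rows per
generic profile (both channels) and at 200-subject subsamples of the
50,000-row SD-sweep datasets, with a single repeat and a 30-epoch
optimisation budget — the orderings under test are driven by the dataset
variability, not by squeezing the last fraction of a mmHg out of M. The
full 500,000-row profiles are exercised for generation-scale and
distribution checks only.

## Known limitations

- The baseline's exact layer widths, dropout rate and L2 coefficient are
  this package's defaults; M-RMSE values on real data depend on them in
  detail, so published M values from other implementations are treated as
  fixed inputs, not reproduction targets.
- The circadian model is a single cosine with per-subject amplitude and
  phase; real dipping patterns (non-dippers, risers) are not represented.
- ISO-8601 times are converted to minutes since the earliest midnight in
  the file; recordings spanning DST changes are not corrected.
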