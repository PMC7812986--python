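# Methods

## Problem and design

`demandcast` forecasts the daily number of attendances at an emergency
department 1, 3 or 7 days ahead, and — as importantly — provides an
honest harness for deciding *which* forecaster to trust: rolling-origin
backtesting, streaming hyperparameter selection, convex model stacking
and permutation-based attribution. Everything is organized around two
objects: `DemandForecaster` (data + run options) and the
`ForecastResults` its `fit()` returns.

## The synthetic world

Real ED records are confidential, so the package ships a generator
whose *structural mean* for day *t* is additive:

    μ(t) = base + trend(t) + weekday(dow t) + annual(doy t)
           + holiday·1[bank or school holiday] + event(t)
           + β_w · (weather(t) − climatology) + β_f · (flu(t) − climatology)

with

- **base**: 208 patients/day by default (a large acute hospital; a
  106/day preset emulates a smaller one);
- **trend**: piecewise-linear slopes in patients/day/year (default
  −8 then +5, breakpoint at 37.5% of the span), centred to zero mean so
  `base` remains the overall level;
- **weekday effects** (patients, Monday first): +18, +6, +2, 0, −2,
  −10, −14 — Monday peak, weekend trough;
- **annual cycle**: cosine with amplitude 12 peaking in early January
  (winter respiratory season);
- **holiday effect**: +8 on rule-generated bank/school holidays (fixed
  dates + May/August Mondays; school terms as date ranges) — no
  external calendar sources;
- **events**: named surges on rule-derived dates (late-August carnival
  weekend +40, Christmas day −30 by default);
- **weather/flu coupling**: small coefficients on *anomalies* of
  simulated covariates (seasonal sinusoids plus noise; flu is a
  winter-peaked AR(1) clipped to [0, 100]), so coupling terms are
  mean-zero over a year.

Counts are drawn with mean μ and variance φ·μ where φ is the
dispersion *relative to Poisson*: negative binomial for φ > 1 (default
φ = 1.5, residual sd ≈ 18 at μ = 208), Poisson at 1, binomial thinning
below 1, and exactly `round(μ)` at φ = 0. This family is continuous
down to the deterministic limit, which makes noise-free oracle tests
possible. μ is floored at 1 before sampling.

What the generator does **not** emulate: serially correlated demand
shocks (epidemic waves beyond the flu covariate), heteroscedastic
reporting artefacts, structural breaks other than the trend breakpoint,
and any cross-covariate dependence beyond the stated couplings. A green
test on this world therefore establishes that the *machinery* is
correct and that structure of the stated kinds is recovered — not that
any particular hospital is predictable to a given accuracy.

## Model matrix and the origin contract

For horizon *h*, the row for target date *t* has origin *o = t − h*:
`yesterday` is the count at *o* (the most recent observed day — at
multi-day horizons "yesterday" is redefined to the origin value so the
feature is observable at prediction time); `same_day_last_week` is the
count at *t − 7* (observable because h ≤ 7); `average_of_previous_week`
is the mean over *o−6 … o*. Weather and flu "previous day" covariates
use the value at *t − 1* even for h ∈ {3, 7}: the operational assumption
that short-range weather forecasts and search trends are available.
Calendar features (month, day of week, holiday/event flags) are known
in advance and evaluated at *t*.

The `time` feature maps the series onto [−0.5, 0.5] with step
1/length, extrapolated linearly beyond the end; any affine convention
is equivalent for the learners used, and this one is declared and
tested. Categorical features are stored as categories; linear/kernel
learners get one-hot indicators with January/Monday reference levels,
tree learners get integer codes.

## Learners

Estimation is delegated to statsmodels (SARIMAX, Holt–Winters, STL,
unobserved-components) and scikit-learn (linear regression, elastic
net, random forest, gradient boosting, k-NN); the package owns the
adapter contract, the grids and the guarantees. Defaults (no grid is
prescribed by the problem): glmnet mixture {0, 0.5, 1} × 20 log-spaced
penalties; rf max-features {p/3, √p, p} at 500 trees; gbm trees
{100, 300} × depth {1, 3} × learning rate {0.05, 0.1}; knn
k ∈ {3, 5, 7, 9, 15}; `lm` has exactly one empty setting. glmnet and
knn are standardized in-pipeline; an exactly zero penalty falls back to
ordinary least squares.

Time-series learners fit on the demand column alone and forecast h
steps past their origin (multi-day horizons are direct, not recursive;
`stlm` re-seasonalizes with the last fitted weekly cycle). ML learners
forecast directly from the horizon-specific feature row. Constant
training windows short-circuit to a constant forecaster for the
time-series family (every mean-reverting specification's fixed point);
other estimation failures surface as a `FitFailure` that backtests
record as skipped rows. Negative forecasts are clamped to 0. `rf`/`gbm`
take their random state from the run seed.

## Temporal cross-validation

`make_split_plan(n, test, h, train)` lays out one fold per test day:
target *t*, origin *t − h*, training window of exactly `train` days
ending at the origin; consecutive folds advance by one day. All folds
must fit (the error message reports the maximum feasible width, which
is also the default: `n − test − h + 1`). Blindness is not an
assumption but a tested property: corrupting all demand after a fold's
origin leaves its forecast bit-unchanged, for every learner.

## Hyperparameter selection

The validation panel is a rectangular date × setting table of absolute
errors (dates with any failed fit are excluded). The five batch rules
score each setting on errors dated strictly before the prediction day:
previous day; mean of the past *n* days (default *n* = 7); recursive
EMA (default α = 0.1; α = 1 reduces to previous-day); whole-panel mean;
whole-panel mean with ties broken toward the least complex setting
(fewest trees/neighbours, largest penalty) — a declared approximation
of resampling-library default selection. Remaining ties go to the
lowest setting id in declared grid order. During testing, each day all
settings are refit and their realized errors are appended to the panel,
so later selections see them.

The online method re-selects only at period boundaries: a rolling
validation backtest of `val_length` one-day folds ending just before
the boundary, whole-panel-mean selection, one refit; the
boundary-fitted model serves every day of the period (time-series
learners forecast `h + offset` steps; ML learners score each day's own
row). Selection events number ⌈test/period⌉.

## Stacking

Weights solve min ‖Pw − y‖² over the simplex — an exact convex QP
(SLSQP from the uniform start, ftol 1e−14, followed by clipping,
renormalization and zeroing of weights < 1e−12; rank-deficient inputs
return a valid, deterministically chosen minimizer). A ridge term on
the weights gives the penalized variant (`ridge=` option). The fitting
rows are validation-block predictions generated by the *same* process
that produces the test predictions: under the batch regime, each
validation day uses the setting the rule would have chosen from
strictly earlier errors (the first validation day is dropped); under
the online regime, the panel-average setting. The weights are then
applied unchanged to the untouched test block. Because every vertex is
feasible, the stack's in-sample squared error never exceeds the best
single learner's, and its forecasts always lie within the
componentwise range of its members.

## Evaluation

MAE is mean |a − p| in patients; MAPE is 100·mean(|a − p| / a) and
requires strictly positive actuals (zero-count days cannot be
percentage-scored). Scoreboards aggregate forecast logs per
configuration and sort ascending by MAE. Permutation importance
shuffles one feature column at a time (a categorical column moves as a
unit) on held-out rows, averages the MAE increase over 10 repeats
(seeded), floors negatives at 0 and normalizes to percentages; a
completely flat profile falls back to equal shares. It is defined for
the ML family only — time-series learners see no covariates. The
held-out slice defaults to the test period. Diagnostics use loess-based
seasonal-trend decomposition with weekly period (data = trend +
seasonal + remainder exactly), weekday/monthly mean profiles, and the
autocorrelation sequence.

## Numerical and design choices

- Split geometry defaults mirror a 75/25-style split: the full-scale
  design is a 1460-day training window, 730-day validation block and
  730-day test block; scaled runs use 120/60/30.
- The scaled synthetic world used in end-to-end acceptance runs
  excludes one-off annual events: a 120-day training window never
  contains a prior occurrence of an annual surge, so its coefficient is
  unidentifiable at that scale and the surge would make the short test
  block structurally unlike the validation block — unlike the
  full-scale design, whose two-year blocks each contain every annual
  event.
- All randomness flows from one root seed, split per learner stage;
  reruns with the same config and seed are byte-identical.
- Derived output CSVs open with an audit comment line carrying the
  config hash and seed; `metadata.json` records every default left
  open (rule parameters, grids, clamps).

## Known limitations

- No prediction intervals or probabilistic forecasts — point MAE/MAPE
  only.
- Hourly or patient-level granularity is out of scope.
- The caret-style selection rule is an approximation (documented
  above), not an emulation of that library's internals.
- ARIMA order selection uses a fixed declared grid, not an automatic
  search; at very short windows the state-space learners are the slow
  path and may be excluded from scaled runs for budget reasons.
- `knn` degrades when the covariate distribution drifts (its test-block
  weakness in the worked example is typical).
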