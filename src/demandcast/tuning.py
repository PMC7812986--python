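"""Hyperparameter-selection policies over streaming validation errors.

Two regimes share one substrate, a panel of per-setting absolute errors
indexed by validation date:

- the *batch* regime re-selects a setting and refits every test day,
  choosing the setting whose error is smallest (i) on the previous day,
  (ii) over the past n days, (iii) under an exponential moving average,
  (iv) averaged over the whole panel, or (v) averaged over the whole
  panel with ties broken toward the least complex setting (an
  approximation of caret-style resampling selection);
- the *online* regime re-selects and refits only at period boundaries
  (1/7/30/60/365/730-day periods), holding the fitted model fixed in
  between, trading a little accuracy for large compute savings.

Every criterion is computed only from errors dated strictly before the
prediction day; during testing each day's realized errors are appended
to the panel so later selections can use them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import build_model_matrix
from .learners import FitFailure, LearnerSpec, complexity_key, fit, predict
from .series import CovariateCalendar, DemandSeries, ValidationError
from .temporal_cv import SizingError, make_log, make_split_plan, run_backtest

RULE_KINDS = ("previous_day", "past_n_days", "ema", "validation_average", "default_resample")


class SelectionError(ValidationError):
    pass


@dataclass(frozen=True)
class SelectionRule:
    """One of the five batch selection rules.

    ``n`` applies to ``past_n_days`` (default 7); ``alpha`` is the
    exponential-moving-average weight in (0, 1] (default 0.1). With
    ``alpha = 1`` the EMA reduces to ``previous_day``; with ``n`` the
    panel length ``past_n_days`` reduces to ``validation_average``.
    """

    kind: str
    n: int = 7
    alpha: float = 0.1

    def __post_init__(self):
        if self.kind not in RULE_KINDS:
            raise ValidationError(f"unknown rule kind {self.kind!r}; expected {RULE_KINDS}")
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class RefitSchedule:
    """Online-method refit period in days (1, 7, 30, 60, 365 or 730
    in the full-scale study; any period >= 1 is accepted)."""

    period: int

    def __post_init__(self):
        if self.period < 1:
            raise ValidationError("period must be >= 1")


class ValidationErrorPanel:
    """Absolute errors per (validation date, hyperparameter setting).

    Rectangular: dates where any setting failed to fit are excluded.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.dropna(axis=0, how="any").sort_index()
        if frame.index.has_duplicates:
            raise ValidationError("duplicate dates in validation panel")
        self.frame = frame

    @classmethod
    def from_log(cls, log: pd.DataFrame) -> "ValidationErrorPanel":
        ok = log[log["status"] == "ok"]
        wide = ok.pivot(index="target_date", columns="hyperparam_id", values="absolute_error")
        return cls(wide)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def setting_ids(self) -> list[int]:
        return list(self.frame.columns)

    def before(self, as_of) -> pd.DataFrame:
        return self.frame[self.frame.index < pd.Timestamp(as_of)]

    def append_day(self, date, errors: dict[int, float]) -> "ValidationErrorPanel":
        row = pd.DataFrame(errors, index=[pd.Timestamp(date)])
        return ValidationErrorPanel(pd.concat([self.frame, row]))


def _criterion(errors: pd.DataFrame, rule: SelectionRule) -> pd.Series:
    if rule.kind == "previous_day":
        return errors.iloc[-1]
    if rule.kind == "past_n_days":
        return errors.iloc[-rule.n :].mean()
    if rule.kind == "ema":
        # recursive EMA down the date axis: e_t = alpha*err_t + (1-alpha)*e_{t-1}
        return errors.ewm(alpha=rule.alpha, adjust=False).mean().iloc[-1]
    # validation_average and default_resample share the mean criterion
    return errors.mean()


def select_hyperparams(
    panel: ValidationErrorPanel,
    rule: SelectionRule,
    as_of,
    spec: LearnerSpec | None = None,
) -> int:
    """Setting minimizing the rule's criterion on errors dated < as_of.

    Ties break toward the least complex setting for ``default_resample``
    (when the spec is supplied), then toward the lowest hyperparam id.
    """
    errors = panel.before(as_of)
    if errors.empty:
        raise SelectionError(f"no validation errors before {pd.Timestamp(as_of).date()}")
    crit = _criterion(errors, rule)
    best = crit.min()
    candidates = sorted(crit.index[crit == best])
    if rule.kind == "default_resample" and spec is not None and len(candidates) > 1:
        grid = spec.settings
        candidates.sort(key=lambda i: (complexity_key(spec.name, grid[i]), i))
    return int(candidates[0])


# ---------------------------------------------------------------------------
# geometry shared by both methods


def _check_geometry(n_total, train_length, val_length, test_length, horizon):
    first_val_target = n_total - test_length - val_length + 1
    need = train_length + horizon + val_length + test_length
    # the matrix additionally needs 7 lag days before the first train row
    if first_val_target - horizon - train_length + 1 < 8:
        raise SizingError(
            f"infeasible geometry: train {train_length} + horizon {horizon} + "
            f"validation {val_length} + test {test_length} needs at least "
            f"{need + 7} days, series has {n_total}"
        )


def _fit_all_settings(spec, train_rows, seed):
    fitted, failures = {}, {}
    for hp_id, params in enumerate(spec.settings):
        try:
            fitted[hp_id] = fit(spec, params, train_rows, seed=seed)
        except FitFailure as exc:
            failures[hp_id] = str(exc)
    return fitted, failures


def run_batch_method(
    series: DemandSeries,
    calendar: CovariateCalendar,
    spec: LearnerSpec,
    rule: SelectionRule,
    horizon: int = 1,
    train_length: int = 1460,
    val_length: int = 730,
    test_length: int = 730,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily re-selection and refit over the test block.

    Builds the validation panel with a rolling-origin backtest over the
    validation block, then for each test day selects a setting via the
    rule (errors strictly before that day), refits it on the trailing
    training window and logs one record. All settings are also refit and
    scored each day so their realized errors roll into the panel.

    Returns (forecast log, selection trace).
    """
    n = len(series)
    horizon = int(horizon)
    _check_geometry(n, train_length, val_length, test_length, horizon)
    matrix = build_model_matrix(series, calendar, horizon)
    # validation block: the val_length days before the test block
    val_plan = make_split_plan(
        n - test_length, val_length, horizon, train_length, start_date=series.start_date
    )
    val_log = run_backtest(val_plan, spec, matrix, seed=seed)
    panel = ValidationErrorPanel.from_log(val_log)
    if len(panel) == 0:
        raise SelectionError(f"{spec.name}: every validation fit failed")

    by_date = matrix.set_index("date", drop=False)
    records, trace = [], []
    grid = spec.settings
    for target in range(n - test_length + 1, n + 1):
        d_target = series.start_date + pd.Timedelta(days=target - 1)
        origin = target - horizon
        d_origin = series.start_date + pd.Timedelta(days=origin - 1)
        d_train_start = d_origin - pd.Timedelta(days=train_length - 1)
        chosen = select_hyperparams(panel, rule, d_target, spec)
        train_rows = matrix[(matrix["date"] >= d_train_start) & (matrix["date"] <= d_origin)]
        target_row = by_date.loc[[d_target]]
        actual = float(target_row["demand"].iloc[0])
        fitted, failures = _fit_all_settings(spec, train_rows, seed)
        day_errors = {}
        for hp_id in fitted:
            pred = predict(
                fitted[hp_id],
                target_row,
                horizon=horizon if spec.family == "time_series" else None,
            )
            day_errors[hp_id] = abs(pred - actual)
            if hp_id == chosen:
                records.append(
                    {
                        "target_date": d_target,
                        "horizon": horizon,
                        "learner": spec.name,
                        "hyperparam_id": hp_id,
                        "params": repr(grid[hp_id]),
                        "prediction": pred,
                        "actual": actual,
                        "absolute_error": abs(pred - actual),
                        "status": "ok",
                        "reason": "",
                    }
                )
        if chosen in failures:
            records.append(
                {
                    "target_date": d_target,
                    "horizon": horizon,
                    "learner": spec.name,
                    "hyperparam_id": chosen,
                    "params": repr(grid[chosen]),
                    "prediction": np.nan,
                    "actual": actual,
                    "absolute_error": np.nan,
                    "status": "skipped",
                    "reason": failures[chosen],
                }
            )
        trace.append({"date": d_target, "hyperparam_id": chosen, "params": repr(grid[chosen])})
        if len(day_errors) == len(grid):  # keep the panel rectangular
            panel = panel.append_day(d_target, day_errors)
    return make_log(records), pd.DataFrame(trace)


def run_online_method(
    series: DemandSeries,
    calendar: CovariateCalendar,
    spec: LearnerSpec,
    schedule: RefitSchedule,
    horizon: int = 1,
    train_length: int = 1460,
    val_length: int = 730,
    test_length: int = 730,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Periodic re-selection with a rolling origin.

    At each period boundary the hyperparameters are re-selected by mean
    error over a rolling validation backtest of ``val_length`` one-day
    folds ending just before the boundary, and the model is refit once;
    within a period the boundary-fitted model serves every day (the
    time-series family forecasts ``horizon + offset`` steps, the ML
    family scores each day's own feature row).

    Returns (forecast log, selection trace). Selection events number
    ``ceil(test_length / period)``.
    """
    n = len(series)
    horizon = int(horizon)
    period = int(schedule.period)
    _check_geometry(n, train_length, val_length, test_length, horizon)
    matrix = build_model_matrix(series, calendar, horizon)
    by_date = matrix.set_index("date", drop=False)
    grid = spec.settings
    records, trace = [], []
    first_test = n - test_length + 1
    for block_start in range(first_test, n + 1, period):
        block_end = min(block_start + period - 1, n)
        # rolling validation block ends just before this boundary
        val_plan = make_split_plan(
            block_start - 1, val_length, horizon, train_length,
            start_date=series.start_date,
        )
        val_log = run_backtest(val_plan, spec, matrix, seed=seed)
        panel = ValidationErrorPanel.from_log(val_log)
        if len(panel) == 0:
            raise SelectionError(f"{spec.name}: every validation fit failed")
        d_boundary = series.start_date + pd.Timedelta(days=block_start - 1)
        chosen = select_hyperparams(
            panel, SelectionRule("validation_average"), d_boundary, spec
        )
        trace.append({"date": d_boundary, "hyperparam_id": chosen, "params": repr(grid[chosen])})
        origin = block_start - horizon
        d_origin = series.start_date + pd.Timedelta(days=origin - 1)
        d_train_start = d_origin - pd.Timedelta(days=train_length - 1)
        train_rows = matrix[(matrix["date"] >= d_train_start) & (matrix["date"] <= d_origin)]
        base = {
            "horizon": horizon,
            "learner": spec.name,
            "hyperparam_id": chosen,
            "params": repr(grid[chosen]),
        }
        try:
            fitted = fit(spec, grid[chosen], train_rows, seed=seed)
        except FitFailure as exc:
            for target in range(block_start, block_end + 1):
                d_target = series.start_date + pd.Timedelta(days=target - 1)
                records.append(
                    {**base, "target_date": d_target,
                     "prediction": np.nan,
                     "actual": float(by_date.loc[d_target, "demand"]),
                     "absolute_error": np.nan, "status": "skipped", "reason": str(exc)}
                )
            continue
        for target in range(block_start, block_end + 1):
            d_target = series.start_date + pd.Timedelta(days=target - 1)
            target_row = by_date.loc[[d_target]]
            actual = float(target_row["demand"].iloc[0])
            if spec.family == "time_series":
                pred = predict(fitted, horizon=horizon + (target - block_start))
            else:
                pred = predict(fitted, target_row)
            records.append(
                {**base, "target_date": d_target, "prediction": pred, "actual": actual,
                 "absolute_error": abs(pred - actual), "status": "ok", "reason": ""}
            )
    return make_log(records), pd.DataFrame(trace)
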