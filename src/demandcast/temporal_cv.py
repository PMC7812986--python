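"""Rolling-origin temporal cross-validation.

Each fold is a fixed-width training window ending at an *origin*, plus
a single one-day test set ``horizon`` days past the origin. Consecutive
folds advance the origin by one day, so every day of the evaluation
block is scored at every horizon while the training window keeps a
constant length. Forecast errors are blind to held-out data by
construction: a fold's fit sees only matrix rows whose target (and
hence all lag features) lies at or before its origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .learners import FitFailure, LearnerSpec, fit, predict
from .series import DemandSeries, ValidationError

#: columns of the forecast log, the substrate for tuning/stacking/scoring
LOG_COLUMNS = (
    "target_date",
    "horizon",
    "learner",
    "hyperparam_id",
    "params",
    "prediction",
    "actual",
    "absolute_error",
    "status",
    "reason",
)


class SizingError(ValidationError):
    pass


@dataclass(frozen=True)
class SplitPlan:
    """Rolling-origin fold layout in 1-based day indices.

    ``folds`` is an ordered list of (train_start, origin, target) day
    numbers with ``target = origin + horizon``; attach ``start_date`` to
    map day 1 onto a calendar date.
    """

    horizon: int
    train_length: int
    folds: tuple[tuple[int, int, int], ...]
    start_date: pd.Timestamp | None = None

    @property
    def test_length(self) -> int:
        return len(self.folds)

    def date_of(self, day: int) -> pd.Timestamp:
        if self.start_date is None:
            raise ValidationError("plan has no start_date attached")
        return self.start_date + pd.Timedelta(days=day - 1)

    def with_start(self, start_date) -> "SplitPlan":
        return SplitPlan(
            self.horizon, self.train_length, self.folds, pd.Timestamp(start_date)
        )


def make_split_plan(
    n_total: int,
    test_length: int,
    horizon: int,
    train_length: int | None = None,
    start_date=None,
) -> SplitPlan:
    """Lay out rolling-origin folds over ``n_total`` consecutive days.

    The last ``test_length`` days are scored, one fold per day; each
    fold trains on the ``train_length`` days ending at its origin
    (``target - horizon``). ``train_length`` defaults to the maximum
    feasible width, ``n_total - test_length - horizon + 1`` — the
    75/25-style split arithmetic for a one-day horizon.
    """
    n_total, test_length, horizon = int(n_total), int(test_length), int(horizon)
    if test_length < 1:
        raise SizingError("test_length must be >= 1")
    if horizon < 1:
        raise SizingError("horizon must be >= 1")
    max_train = n_total - test_length - horizon + 1
    if train_length is None:
        train_length = max_train
    train_length = int(train_length)
    if train_length < 1 or train_length > max_train:
        raise SizingError(
            f"infeasible split geometry: with n_total={n_total}, "
            f"test_length={test_length}, horizon={horizon} the maximum feasible "
            f"train_length is {max_train} (got {train_length})"
        )
    first_target = n_total - test_length + 1
    folds = []
    for target in range(first_target, n_total + 1):
        origin = target - horizon
        folds.append((origin - train_length + 1, origin, target))
    plan = SplitPlan(horizon, train_length, tuple(folds))
    return plan.with_start(start_date) if start_date is not None else plan


def plan_for_series(
    series: DemandSeries, test_length: int, horizon: int, train_length: int | None = None
) -> SplitPlan:
    return make_split_plan(
        len(series), test_length, horizon, train_length, start_date=series.start_date
    )


def empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=list(LOG_COLUMNS))


def make_log(records: list[dict]) -> pd.DataFrame:
    log = pd.DataFrame(records, columns=list(LOG_COLUMNS))
    if len(log):
        dup = log.duplicated(subset=["target_date", "horizon", "learner", "hyperparam_id"])
        if dup.any():
            raise ValidationError("duplicate (date, learner, hyperparam) records in log")
    return log


def run_backtest(
    plan: SplitPlan,
    spec: LearnerSpec,
    matrix: pd.DataFrame,
    seed: int = 0,
    settings: list[int] | None = None,
) -> pd.DataFrame:
    """Execute every fold x hyperparameter setting; return the forecast log.

    Fit failures are recorded as skipped rows (with the reason) rather
    than aborting a long run. ``settings`` restricts the grid to the
    given hyperparam ids.
    """
    if plan.start_date is None:
        raise ValidationError("plan must carry a start_date (use plan_for_series)")
    if int(matrix["horizon"].iloc[0]) != plan.horizon:
        raise ValidationError("matrix horizon does not match plan horizon")
    by_date = matrix.set_index("date", drop=False)
    grid = spec.settings
    ids = range(len(grid)) if settings is None else settings
    records = []
    for train_start, origin, target in plan.folds:
        d_start, d_origin, d_target = (plan.date_of(d) for d in (train_start, origin, target))
        train_rows = matrix[(matrix["date"] >= d_start) & (matrix["date"] <= d_origin)]
        try:
            target_row = by_date.loc[[d_target]]
        except KeyError:
            raise ValidationError(f"matrix has no row for target {d_target.date()}")
        actual = float(target_row["demand"].iloc[0])
        for hp_id in ids:
            records.append(
                _score_one(
                    spec, hp_id, grid[hp_id], train_rows, target_row,
                    plan.horizon, d_target, actual, seed,
                )
            )
    return make_log(records)


def _score_one(spec, hp_id, params, train_rows, target_row, horizon, d_target, actual, seed):
    base = {
        "target_date": d_target,
        "horizon": horizon,
        "learner": spec.name,
        "hyperparam_id": hp_id,
        "params": repr(params),
        "actual": actual,
    }
    try:
        fitted = fit(spec, params, train_rows, seed=seed)
        pred = predict(fitted, target_row, horizon=horizon if spec.family == "time_series" else None)
    except FitFailure as exc:
        return {**base, "prediction": np.nan, "absolute_error": np.nan,
                "status": "skipped", "reason": str(exc)}
    err = abs(pred - actual) if np.isfinite(actual) else np.nan
    return {**base, "prediction": pred, "absolute_error": err, "status": "ok", "reason": ""}
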