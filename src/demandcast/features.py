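"""Model-matrix construction with a strict no-leakage origin contract.

Each row describes one target date at a given horizon h. The *origin*
is the last observed day, ``target - h``; every lagged-demand feature
is a function only of counts dated <= origin:

- ``yesterday``: the count at the origin (the most recent observed day;
  at h = 1 this is literally the day before the target).
- ``same_day_last_week``: the count at target - 7 days (observable for
  every supported horizon since h <= 7).
- ``average_of_previous_week``: mean of the 7 most recent observed
  counts (origin - 6 .. origin).

Weather and flu covariates "on the previous day" use the value at
target - 1 even for multi-day horizons — the operational assumption
that short-range weather forecasts and search trends are available at
prediction time. Calendar features (month, day of week, holiday and
event flags) are known in advance and evaluated at the target date.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .series import CovariateCalendar, DemandSeries, ValidationError

SUPPORTED_HORIZONS = (1, 3, 7)

MONTHS = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)
DAYS_OF_WEEK = (
    "Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday",
)

#: fixed, documented column order of the emitted matrix
MATRIX_COLUMNS = (
    "date",
    "demand",
    "month",
    "yesterday",
    "same_day_last_week",
    "average_of_previous_week",
    "time",
    "bank_holiday",
    "school_holiday",
    "day_of_week",
    "precipitation_prev_day",
    "tmax_prev_day",
    "tmin_prev_day",
    "flu_hits_prev_day",
    "horizon",
    "origin",
)

#: numeric/flag feature columns used by ML learners (event flags appended)
FEATURE_COLUMNS = (
    "month",
    "yesterday",
    "same_day_last_week",
    "average_of_previous_week",
    "time",
    "bank_holiday",
    "school_holiday",
    "day_of_week",
    "precipitation_prev_day",
    "tmax_prev_day",
    "tmin_prev_day",
    "flu_hits_prev_day",
)


class UnsupportedHorizonError(ValidationError):
    pass


class AlignmentError(ValidationError):
    pass


def scaled_time_index(train_window_length: int, position) -> np.ndarray | float:
    """Dimensionless linear time feature.

    Maps positions 1..L of a training window of length L onto
    [-0.5, 0.5] (midpoint -> 0, step exactly 1/L) and extrapolates
    linearly for positions beyond the window (forecast targets).
    """
    L = int(train_window_length)
    if L <= 0:
        raise ValidationError("train_window_length must be positive")
    pos = np.asarray(position, dtype=float)
    out = (pos - (L + 1) / 2.0) / L
    return float(out) if out.ndim == 0 else out


def build_model_matrix(
    series: DemandSeries,
    calendar: CovariateCalendar,
    horizon: int,
    include_future: bool = True,
) -> pd.DataFrame:
    """Assemble the per-target-date feature matrix for one horizon.

    Rows cover every target date whose lag features are observable
    (target - 7 and origin - 6 inside the series). With
    ``include_future`` the h dates after the series end are included
    with ``demand`` = NaN — these are the rows one actually predicts.
    Feature cells are always complete.
    """
    horizon = int(horizon)
    if horizon not in SUPPORTED_HORIZONS:
        raise UnsupportedHorizonError(
            f"horizon {horizon} unsupported; expected one of {SUPPORTED_HORIZONS}"
        )
    if len(series) < 7 + horizon:
        raise ValidationError(f"series too short ({len(series)} days) for horizon {horizon}")
    if not calendar.aligned_with(series):
        raise AlignmentError("calendar and series must cover the same date span")

    n = len(series)
    counts = series.counts.astype(float)
    start = series.start_date
    # target offsets (0-based day index relative to start); first eligible
    # target needs origin-6 >= 0 and target-7 >= 0
    first = max(horizon + 6, 7)
    last = n - 1 + (horizon if include_future else 0)
    targets = np.arange(first, last + 1)
    origins = targets - horizon

    dates = start + pd.to_timedelta(targets, unit="D")
    origin_dates = start + pd.to_timedelta(origins, unit="D")
    demand = np.where(targets < n, counts[np.minimum(targets, n - 1)], np.nan)

    prev_week = np.lib.stride_tricks.sliding_window_view(counts, 7).mean(axis=1)
    cal = calendar.frame
    prev_day = np.minimum(targets - 1, n - 1)  # target-1; observable by assumption

    matrix = pd.DataFrame(
        {
            "date": dates,
            "demand": demand,
            "month": pd.Categorical(
                [MONTHS[m - 1] for m in dates.month], categories=MONTHS
            ),
            "yesterday": counts[origins],
            "same_day_last_week": counts[targets - 7],
            "average_of_previous_week": prev_week[origins - 6],
            "time": scaled_time_index(n, targets + 1),
            "bank_holiday": _at(cal, "bank_holiday", dates),
            "school_holiday": _at(cal, "school_holiday", dates),
            "day_of_week": pd.Categorical(
                [DAYS_OF_WEEK[d] for d in dates.dayofweek], categories=DAYS_OF_WEEK
            ),
            "precipitation_prev_day": cal["precipitation"].to_numpy()[prev_day],
            "tmax_prev_day": cal["tmax"].to_numpy()[prev_day],
            "tmin_prev_day": cal["tmin"].to_numpy()[prev_day],
            "flu_hits_prev_day": cal["flu_hits"].to_numpy()[prev_day],
            "horizon": horizon,
            "origin": origin_dates,
        }
    )
    for col in calendar.event_columns:
        matrix[col] = _at(cal, col, dates)
    return matrix.reset_index(drop=True)


def _at(cal: pd.DataFrame, column: str, dates: pd.DatetimeIndex) -> np.ndarray:
    """Calendar value at the target date; dates past the calendar end fall
    back to the rule value False/last observation (future flags are known
    in principle; the synthetic calendar simply may stop at the series
    end)."""
    values = cal[column].to_numpy()
    idx = cal.index.get_indexer(dates)
    out = np.empty(len(dates), dtype=values.dtype)
    inside = idx >= 0
    out[inside] = values[idx[inside]]
    if not inside.all():
        out[~inside] = False if values.dtype == bool else values[-1]
    return out


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """The covariate columns (fixed order, event flags last)."""
    extra = [
        c for c in matrix.columns if c not in MATRIX_COLUMNS and c not in ("date",)
    ]
    return list(FEATURE_COLUMNS) + extra


def matrix_to_csv(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    for col in ("date", "origin"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def matrix_from_csv(path) -> pd.DataFrame:
    matrix = pd.read_csv(path)
    for col in ("date", "origin"):
        matrix[col] = pd.to_datetime(matrix[col], format="%Y-%m-%d")
    matrix["month"] = pd.Categorical(matrix["month"], categories=MONTHS)
    matrix["day_of_week"] = pd.Categorical(matrix["day_of_week"], categories=DAYS_OF_WEEK)
    return matrix
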