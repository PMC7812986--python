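"""Core data containers: daily demand series and covariate calendars.

Both containers are thin, validated wrappers around pandas objects with
CSV round-tripping. Dates are always consecutive calendar days — the
rolling-origin machinery downstream relies on a gap-free daily index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: covariate columns every calendar must carry; extra event-flag columns
#: (carnival, christmas, ...) are allowed and preserved.
BASE_COVARIATES = (
    "bank_holiday",
    "school_holiday",
    "precipitation",
    "tmax",
    "tmin",
    "flu_hits",
)


class ValidationError(ValueError):
    """Raised when a container or config violates its invariants."""


def _daily_index(start: pd.Timestamp, n: int) -> pd.DatetimeIndex:
    return pd.date_range(start=start, periods=n, freq="D")


@dataclass(frozen=True)
class DemandSeries:
    """Consecutive daily attendance counts — the forecasting target.

    Parameters
    ----------
    start_date : date-like
        Calendar date of the first observation.
    counts : array-like of int
        One non-negative attendance count per consecutive calendar day.
    """

    start_date: pd.Timestamp
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "start_date", pd.Timestamp(self.start_date).normalize())
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or len(counts) == 0:
            raise ValidationError("counts must be a non-empty 1-d array")
        if not np.all(np.isfinite(counts)):
            raise ValidationError("counts must be finite")
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValidationError("counts must be integers (patients/day)")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        self.counts.setflags(write=False)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return _daily_index(self.start_date, len(self.counts))

    @property
    def end_date(self) -> pd.Timestamp:
        return self.dates[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "count": self.counts})

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.dates, name="count")

    def value_at(self, date) -> int:
        date = pd.Timestamp(date).normalize()
        offset = (date - self.start_date).days
        if not 0 <= offset < len(self.counts):
            raise KeyError(f"date {date.date()} outside series span")
        return int(self.counts[offset])

    def slice(self, start, end) -> "DemandSeries":
        """Sub-series covering [start, end] inclusive."""
        start = pd.Timestamp(start).normalize()
        end = pd.Timestamp(end).normalize()
        i = (start - self.start_date).days
        j = (end - self.start_date).days
        if i < 0 or j >= len(self.counts) or j < i:
            raise ValidationError("slice outside series span")
        return DemandSeries(start, self.counts[i : j + 1])

    # -- CSV I/O -----------------------------------------------------------

    def to_csv(self, path) -> None:
        self.to_frame().assign(date=lambda d: d["date"].dt.strftime("%Y-%m-%d")).to_csv(
            path, index=False
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DemandSeries":
        if not {"date", "count"} <= set(frame.columns):
            raise ValidationError("series frame needs 'date' and 'count' columns")
        dates = pd.to_datetime(frame["date"]).dt.normalize()
        _check_consecutive(dates)
        return cls(dates.iloc[0], frame["count"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "DemandSeries":
        return cls.from_frame(_read_dated_csv(path))


@dataclass(frozen=True)
class CovariateCalendar:
    """Daily covariates accompanying a demand series.

    Holds, per date: bank/school-holiday flags, named event flags,
    precipitation (mm), max/min temperature (degC) and relative flu
    search volume in [0, 100].
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        frame = self.frame.copy()
        if not isinstance(frame.index, pd.DatetimeIndex):
            raise ValidationError("calendar frame must be indexed by date")
        frame.index = frame.index.normalize()
        _check_consecutive(pd.Series(frame.index))
        missing = set(BASE_COVARIATES) - set(frame.columns)
        if missing:
            raise ValidationError(f"calendar missing columns: {sorted(missing)}")
        if (frame["precipitation"] < 0).any():
            raise ValidationError("precipitation must be >= 0")
        if (frame["tmin"] > frame["tmax"]).any():
            raise ValidationError("tmin must be <= tmax on every date")
        if ((frame["flu_hits"] < 0) | (frame["flu_hits"] > 100)).any():
            raise ValidationError("flu_hits must lie in [0, 100]")
        for col in self.flag_columns_of(frame):
            frame[col] = frame[col].astype(bool)
        object.__setattr__(self, "frame", frame)

    @staticmethod
    def flag_columns_of(frame: pd.DataFrame) -> list[str]:
        numeric = {"precipitation", "tmax", "tmin", "flu_hits"}
        return [c for c in frame.columns if c not in numeric]

    @property
    def event_columns(self) -> list[str]:
        return [
            c
            for c in self.flag_columns_of(self.frame)
            if c not in ("bank_holiday", "school_holiday")
        ]

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    def __len__(self) -> int:
        return len(self.frame)

    def aligned_with(self, series: DemandSeries) -> bool:
        return len(self) == len(series) and self.dates[0] == series.start_date

    def to_csv(self, path) -> None:
        out = self.frame.reset_index(names="date")
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CovariateCalendar":
        frame = _read_dated_csv(path)
        frame["date"] = pd.to_datetime(frame["date"]).dt.normalize()
        return cls(frame.set_index("date"))


def _check_consecutive(dates: pd.Series) -> None:
    dates = pd.Series(pd.to_datetime(dates).to_numpy())
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise ValidationError(f"duplicate date {pd.Timestamp(dup).date()}")
    gaps = dates.diff().dropna()
    bad = gaps[gaps != pd.Timedelta(days=1)]
    if len(bad):
        i = bad.index[0]
        missing = dates.iloc[i - 1] + pd.Timedelta(days=1)
        raise ValidationError(
            f"date gap after {dates.iloc[i - 1].date()}: missing {missing.date()}"
        )


def _read_dated_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if "date" not in frame.columns:
        raise ValidationError(f"{path}: missing 'date' column in header")
    try:
        frame["date"] = pd.to_datetime(frame["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non ISO-8601 date — {exc}") from exc
    return frame
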