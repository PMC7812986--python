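"""Synthetic ED-attendance generator.

Emulates the statistical structure of daily attendance at large London
emergency departments: a slowly varying (piecewise-linear) trend, strong
day-of-week structure with a Monday peak and weekend troughs, a
winter-peaked annual cycle, bank/school-holiday and one-off event
effects, weak coupling to weather and flu-search activity, and
overdispersed count noise around mean levels of roughly 100-210
patients/day.

Effects combine additively on the mean scale. The count noise has
mean ``mu`` and variance ``dispersion * mu`` (dispersion is relative to
Poisson: negative binomial above 1, Poisson at 1, binomial thinning
below 1, and the ``dispersion -> 0`` limit is the deterministic
``round(mu)`` series).
Weather and flu covariates are simulated as seasonal sinusoids plus
noise; only their (anomaly-scaled) coupling into demand matters for the
downstream machinery. Holiday calendars come from configurable date
rules, never from external sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .series import CovariateCalendar, DemandSeries, ValidationError

# climatological anchors used to centre the covariate couplings so that
# coupling terms have (approximately) zero mean over a full year
PRECIP_MEAN = 1.35  # mm/day
TMAX_MEAN = 14.0  # degC
TMIN_MEAN = 8.0  # degC
FLU_MEAN = 20.0  # relative search volume

_WEEKDAYS = ("monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday")


def _last_weekday_of_month(year: int, month: int, weekday: int) -> pd.Timestamp:
    last = pd.Timestamp(year=year, month=month, day=1) + pd.offsets.MonthEnd(0)
    return last - pd.Timedelta(days=(last.dayofweek - weekday) % 7)


def default_bank_holidays(year: int) -> list[pd.Timestamp]:
    """UK-like bank-holiday rule set (fixed dates + May/August Mondays)."""
    first_may_monday = pd.Timestamp(year=year, month=5, day=1)
    first_may_monday += pd.Timedelta(days=(7 - first_may_monday.dayofweek) % 7)
    return [
        pd.Timestamp(year=year, month=1, day=1),
        first_may_monday,
        _last_weekday_of_month(year, 5, 0),
        _last_weekday_of_month(year, 8, 0),
        pd.Timestamp(year=year, month=12, day=25),
        pd.Timestamp(year=year, month=12, day=26),
    ]


#: school-holiday blocks as ((start_month, start_day), (end_month, end_day))
DEFAULT_SCHOOL_TERMS = (
    ((12, 20), (1, 5)),   # christmas break (wraps the year end)
    ((2, 14), (2, 21)),   # february half term
    ((4, 1), (4, 14)),    # easter break
    ((5, 28), (6, 3)),    # may half term
    ((7, 20), (9, 1)),    # summer
    ((10, 22), (10, 29)), # autumn half term
)


def default_event_rules(year: int) -> dict[str, list[pd.Timestamp]]:
    """Named surge events: the late-August carnival weekend and Christmas day."""
    aug_monday = _last_weekday_of_month(year, 8, 0)
    return {
        "carnival": [aug_monday - pd.Timedelta(days=1), aug_monday],
        "christmas": [pd.Timestamp(year=year, month=12, day=25)],
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world for the attendance generator.

    Parameters
    ----------
    n_days : int
        Length of the simulated span.
    base_level : float
        Mean patients/day when every effect is zero.
    trend_slopes : sequence of float
        Piecewise-linear slopes in patients/day/year; segment boundaries
        given by ``trend_breakpoints`` (fractions of the span). The
        trend is centred to zero mean over the span so ``base_level``
        stays the overall level.
    weekday_effects : 7 floats
        Additive offsets (patients), Monday first. Default peaks on
        Monday and dips at the weekend.
    annual_amplitude : float
        Patients; cosine annual cycle peaking in early January (winter).
    holiday_effect : float
        Additive offset on bank or school holidays.
    event_effects : mapping name -> surge (patients)
        Applied on the dates produced by the named event rule.
    weather_coupling : (precip, tmax, tmin) coefficients
        Patients per unit anomaly of the covariate.
    flu_coupling : float
        Patients per unit anomaly of flu search volume.
    dispersion : float
        Count-noise variance relative to Poisson: variance =
        dispersion * mu. Above 1 (the default) the counts are
        overdispersed negative binomial; 0 switches noise off
        (deterministic round(mu)).
    seed : int
        Root seed; identical config + seed gives bit-identical output.
    """

    n_days: int = 2920
    start_date: str = "2011-01-03"  # a Monday
    base_level: float = 208.0
    trend_slopes: Sequence[float] = (-8.0, 5.0)
    trend_breakpoints: Sequence[float] = (0.375,)
    weekday_effects: Sequence[float] = (18.0, 6.0, 2.0, 0.0, -2.0, -10.0, -14.0)
    annual_amplitude: float = 12.0
    winter_peak_doy: int = 10
    holiday_effect: float = 8.0
    event_effects: Mapping[str, float] = field(
        default_factory=lambda: {"carnival": 40.0, "christmas": -30.0}
    )
    weather_coupling: Sequence[float] = (0.3, -0.4, 0.0)
    flu_coupling: float = 0.25
    dispersion: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if int(self.n_days) < 1:
            raise ValidationError("n_days: must be >= 1")
        if not self.base_level > 0:
            raise ValidationError("base_level: must be > 0")
        if self.dispersion < 0:
            raise ValidationError("dispersion: must be >= 0")
        if len(self.weekday_effects) != 7:
            raise ValidationError("weekday_effects: exactly 7 entries required")
        if len(self.trend_slopes) != len(self.trend_breakpoints) + 1:
            raise ValidationError(
                "trend_slopes: need exactly one more slope than trend_breakpoints"
            )
        if len(self.weather_coupling) != 3:
            raise ValidationError("weather_coupling: (precip, tmax, tmin) required")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=int(self.n_days), freq="D")

    def replace(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


def st_marys_like() -> SyntheticConfig:
    """Default config calibrated to a large acute ED (mean ~208/day)."""
    return SyntheticConfig()


def charing_cross_like() -> SyntheticConfig:
    """Config for a smaller ED (mean ~106/day, upward trend)."""
    return SyntheticConfig(
        base_level=106.0,
        trend_slopes=(4.0,),
        trend_breakpoints=(),
        weekday_effects=(10.0, 3.0, 1.0, 0.0, -1.0, -6.0, -7.0),
        annual_amplitude=6.0,
        event_effects={"carnival": 15.0, "christmas": -15.0},
    )


# ---------------------------------------------------------------------------
# deterministic structure


def _trend_values(config: SyntheticConfig) -> np.ndarray:
    n = int(config.n_days)
    t = np.arange(n, dtype=float)
    daily = np.empty(n)
    bounds = [0.0, *config.trend_breakpoints, 1.0]
    cut = [int(round(b * n)) for b in bounds]
    for slope, lo, hi in zip(config.trend_slopes, cut[:-1], cut[1:]):
        daily[lo:hi] = slope / 365.25
    trend = np.concatenate([[0.0], np.cumsum(daily)[:-1]])
    return trend - trend.mean()  # centre: base_level stays the overall level


def _annual_values(dates: pd.DatetimeIndex, config: SyntheticConfig) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(float)
    return config.annual_amplitude * np.cos(
        2 * np.pi * (doy - config.winter_peak_doy) / 365.25
    )


def _holiday_flags(dates: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
    bank = np.zeros(len(dates), bool)
    for year in range(dates[0].year, dates[-1].year + 1):
        for d in default_bank_holidays(year):
            loc = dates.get_indexer([d])
            if loc[0] >= 0:
                bank[loc[0]] = True
    school = np.zeros(len(dates), bool)
    md = list(zip(dates.month, dates.day))
    for (sm, sd), (em, ed) in DEFAULT_SCHOOL_TERMS:
        if (sm, sd) <= (em, ed):
            school |= np.array([(sm, sd) <= x <= (em, ed) for x in md])
        else:  # wraps the year boundary
            school |= np.array([x >= (sm, sd) or x <= (em, ed) for x in md])
    return bank, school


def _event_flags(dates: pd.DatetimeIndex, config: SyntheticConfig) -> dict[str, np.ndarray]:
    flags = {name: np.zeros(len(dates), bool) for name in config.event_effects}
    for year in range(dates[0].year, dates[-1].year + 1):
        for name, rule_dates in default_event_rules(year).items():
            if name not in flags:
                continue
            for d in rule_dates:
                loc = dates.get_indexer([d])
                if loc[0] >= 0:
                    flags[name][loc[0]] = True
    return flags


def structural_mean(config: SyntheticConfig, date, calendar: CovariateCalendar | None = None):
    """Expected patients/day at ``date`` under the configured structure.

    A pure function of config and date: base level + trend + weekday +
    annual + holiday + event terms. Weather/flu coupling terms use the
    realized covariates when a calendar is supplied; without one they
    contribute zero (couplings act on anomalies about climatology).
    """
    dates = config.dates
    date = pd.Timestamp(date).normalize()
    loc = dates.get_indexer([date])[0]
    if loc < 0:
        raise ValidationError(f"date {date.date()} outside configured span")
    mu = _structural_means(config, calendar)
    return float(mu[loc])


def _structural_means(
    config: SyntheticConfig, calendar: CovariateCalendar | None
) -> np.ndarray:
    dates = config.dates
    mu = np.full(len(dates), float(config.base_level))
    mu += _trend_values(config)
    mu += np.asarray(config.weekday_effects, float)[dates.dayofweek]
    mu += _annual_values(dates, config)
    bank, school = _holiday_flags(dates)
    mu += config.holiday_effect * (bank | school)
    for name, flag in _event_flags(dates, config).items():
        mu += config.event_effects[name] * flag
    if calendar is not None:
        cp, cx, cn = config.weather_coupling
        f = calendar.frame
        mu += cp * (f["precipitation"].to_numpy() - PRECIP_MEAN)
        mu += cx * (f["tmax"].to_numpy() - TMAX_MEAN)
        mu += cn * (f["tmin"].to_numpy() - TMIN_MEAN)
        mu += config.flu_coupling * (f["flu_hits"].to_numpy() - FLU_MEAN)
    return np.maximum(mu, 1.0)  # positive floor before sampling


# ---------------------------------------------------------------------------
# stochastic parts


def _simulate_weather(dates: pd.DatetimeIndex, rng: np.random.Generator):
    doy = dates.dayofyear.to_numpy(float)
    seasonal_tmax = TMAX_MEAN + 8.0 * np.cos(2 * np.pi * (doy - 196) / 365.25)
    tmax = seasonal_tmax + rng.normal(0.0, 2.5, len(dates))
    spread = np.clip(6.0 + rng.normal(0.0, 1.0, len(dates)), 0.5, None)
    tmin = tmax - spread
    wet = rng.random(len(dates)) < 0.45
    precip = np.where(wet, rng.gamma(1.2, 2.5, len(dates)), 0.0)
    return precip, tmax, tmin


def _simulate_flu(dates: pd.DatetimeIndex, rng: np.random.Generator) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(float)
    seasonal = FLU_MEAN + 16.0 * np.cos(2 * np.pi * (doy - 15) / 365.25)
    ar = np.zeros(len(dates))
    eps = rng.normal(0.0, 2.0, len(dates))
    for i in range(1, len(dates)):
        ar[i] = 0.8 * ar[i - 1] + eps[i]
    return np.clip(seasonal + ar, 0.0, 100.0)


def generate(config: SyntheticConfig) -> tuple[DemandSeries, CovariateCalendar]:
    """Simulate a demand series and matching covariate calendar.

    Deterministic given ``config.seed``. Counts are drawn around the
    structural mean with variance ``dispersion * mu`` (negative
    binomial when overdispersed); ``dispersion == 0`` returns
    ``round(mu)`` exactly.
    """
    dates = config.dates
    rng = np.random.default_rng(config.seed)
    precip, tmax, tmin = _simulate_weather(dates, rng)
    flu = _simulate_flu(dates, rng)
    bank, school = _holiday_flags(dates)
    frame = pd.DataFrame(
        {
            "bank_holiday": bank,
            "school_holiday": school,
            "precipitation": np.round(precip, 2),
            "tmax": np.round(tmax, 1),
            "tmin": np.round(tmin, 1),
            "flu_hits": np.round(flu, 2),
        },
        index=dates,
    )
    for name, flag in _event_flags(dates, config).items():
        frame[name] = flag
    calendar = CovariateCalendar(frame)

    mu = _structural_means(config, calendar)
    counts = _draw_counts(mu, config.dispersion, rng)
    return DemandSeries(dates[0], counts), calendar


def _draw_counts(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Counts with mean mu and variance phi*mu.

    phi > 1: negative binomial (theta = mu/(phi-1)); phi = 1: Poisson;
    0 < phi < 1: binomial with p = 1-phi (variance-deflated); phi = 0:
    deterministic round(mu).
    """
    if phi == 0:
        return np.round(mu).astype(np.int64)
    if phi > 1:
        theta = mu / (phi - 1.0)
        return rng.negative_binomial(theta, theta / (theta + mu))
    if phi == 1:
        return rng.poisson(mu)
    p = 1.0 - phi
    return rng.binomial(np.round(mu / p).astype(np.int64), p)
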