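"""Scoring, scoreboards, permutation importance and EDA diagnostics.

MAE is reported in patients, MAPE in percent of actual demand (actuals
must be positive — attendance counts of zero cannot be
percentage-scored). Scoreboards aggregate forecast logs into one row
per configuration, sorted ascending by MAE. Permutation importance
measures the held-out error increase when one predictor's values are
shuffled, floored at zero and normalized to percentages per learner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import feature_columns
from .learners import ContractError, FittedLearner, encode_features
from .series import DemandSeries, ValidationError


def mae(actuals, predictions) -> float:
    """Mean absolute error in patients."""
    a = np.asarray(actuals, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise ValidationError("actuals and predictions must be equal-length, non-empty")
    return float(np.mean(np.abs(a - p)))


def mape(actuals, predictions) -> float:
    """Mean absolute percentage error, in percent of actual demand."""
    a = np.asarray(actuals, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise ValidationError("actuals and predictions must be equal-length, non-empty")
    if np.any(a <= 0):
        raise ValidationError("MAPE undefined: actuals must be strictly positive")
    return float(100.0 * np.mean(np.abs(a - p) / a))


def scoreboard(logs, by: tuple[str, ...] = ("learner", "horizon")) -> pd.DataFrame:
    """Aggregate one or many forecast logs into an error table.

    One row per group (extra grouping keys such as ``rule`` or
    ``period`` are used when present), with MAE, MAPE, the number of
    scored records and the number skipped, sorted ascending by MAE.
    """
    if isinstance(logs, pd.DataFrame):
        logs = [logs]
    log = pd.concat(list(logs), ignore_index=True) if logs else pd.DataFrame()
    if log.empty:
        import warnings

        warnings.warn("empty forecast log: empty scoreboard")
        return pd.DataFrame(columns=[*by, "mae", "mape", "n_records", "n_skipped"])
    keys = [k for k in by if k in log.columns]
    extra = [k for k in ("rule", "period", "method") if k in log.columns and k not in keys]
    keys = keys + extra
    rows = []
    for group, part in log.groupby(keys, dropna=False, sort=False):
        group = group if isinstance(group, tuple) else (group,)
        ok = part[part["status"] == "ok"]
        row = dict(zip(keys, group))
        row["mae"] = mae(ok["actual"], ok["prediction"]) if len(ok) else np.nan
        row["mape"] = mape(ok["actual"], ok["prediction"]) if len(ok) else np.nan
        row["n_records"] = int(len(ok))
        row["n_skipped"] = int((part["status"] != "ok").sum())
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values("mae", na_position="last")
        .reset_index(drop=True)
    )


def permutation_importance(
    fitted: FittedLearner,
    matrix: pd.DataFrame,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation variable importance on a held-out matrix slice.

    For each feature column, its values are shuffled ``repeats`` times
    and the mean MAE increase over the unpermuted baseline is recorded,
    floored at 0, then normalized so the percentages sum to 100.
    Defined for the ML family (the time-series learners see no
    covariates).
    """
    if fitted.family != "ml":
        raise ContractError("permutation importance applies to the ML family")
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    rows = matrix.dropna(subset=["demand"]).reset_index(drop=True)
    if rows.empty:
        raise ValidationError("held-out matrix has no scored rows")
    cols = feature_columns(rows)
    _, est = fitted._state
    name = fitted.spec.name
    y = rows["demand"].to_numpy(dtype=float)
    baseline = mae(y, np.maximum(est.predict(encode_features(rows, name)), 0.0))
    rng = np.random.default_rng(seed)
    increases = {}
    for col in cols:
        if col not in rows.columns:
            raise ContractError(f"feature {col!r} absent from matrix")
        deltas = []
        for _ in range(int(repeats)):
            shuffled = rows.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            pred = np.maximum(est.predict(encode_features(shuffled, name)), 0.0)
            deltas.append(mae(y, pred) - baseline)
        increases[col] = max(0.0, float(np.mean(deltas)))
    total = sum(increases.values())
    k = len(cols)
    if total == 0.0:  # nothing moved the error: flat profile
        pct = {c: 100.0 / k for c in cols}
    else:
        pct = {c: 100.0 * v / total for c, v in increases.items()}
    report = pd.DataFrame(
        {"feature": list(pct), "importance_pct": list(pct.values())}
    ).sort_values("importance_pct", ascending=False, ignore_index=True)
    report.attrs["learner"] = name
    report.attrs["baseline_mae"] = baseline
    return report


@dataclass
class Diagnostics:
    """Exploratory decomposition and profiles of a demand series."""

    trend: pd.Series
    seasonal: pd.Series
    remainder: pd.Series
    weekday_profile: pd.Series
    monthly_profile: pd.Series
    acf: np.ndarray

    def reconstruction(self) -> pd.Series:
        """trend + seasonal + remainder — equals the data exactly."""
        return self.trend + self.seasonal + self.remainder


def diagnostics(
    series: DemandSeries, seasonal_period: int = 7, acf_lags: int = 30
) -> Diagnostics:
    """STL-style additive decomposition plus calendar profiles and the
    autocorrelation sequence.

    The decomposition is loess-based with the weekly period by default
    (data = trend + seasonal + remainder exactly); profiles are mean
    attendance by day of week (Monday first) and by month.
    """
    from statsmodels.tsa.seasonal import STL
    from statsmodels.tsa.stattools import acf as sm_acf

    if len(series) < 2 * seasonal_period + 1:
        raise ValidationError(
            f"series too short for decomposition with period {seasonal_period}"
        )
    if len(series) < 14:
        raise ValidationError("series too short for weekly profiles")
    s = series.to_series().astype(float)
    res = STL(s, period=seasonal_period).fit()
    remainder = s - res.trend - res.seasonal  # exact additive reconstruction
    weekday = s.groupby(s.index.dayofweek).mean()
    weekday.index = pd.Index(
        ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday"]
    )[weekday.index]
    monthly = s.groupby(s.index.month).mean()
    nlags = min(acf_lags, len(s) - 1)
    return Diagnostics(
        trend=res.trend,
        seasonal=res.seasonal,
        remainder=remainder,
        weekday_profile=weekday,
        monthly_profile=monthly,
        acf=sm_acf(s, nlags=nlags, fft=True),
    )


def plot_diagnostics(diag: Diagnostics, path=None):
    """Plain four-panel view: decomposition, weekday and monthly profiles,
    autocorrelation. Returns the figure; saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    data = diag.reconstruction()
    axes[0, 0].plot(data.index, data, lw=0.6, label="data")
    axes[0, 0].plot(diag.trend.index, diag.trend, lw=1.2, label="trend")
    axes[0, 0].legend(fontsize=8)
    axes[0, 0].set_title("attendance and trend")
    diag.weekday_profile.plot.bar(ax=axes[0, 1], title="mean by day of week")
    diag.monthly_profile.plot.bar(ax=axes[1, 0], title="mean by month")
    axes[1, 1].stem(range(len(diag.acf)), diag.acf)
    axes[1, 1].set_title("autocorrelation")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
    return fig
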