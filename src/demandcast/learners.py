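"""Uniform adapter contract over nine daily-demand forecasters.

Two families share one fit/predict surface so the cross-validation,
tuning and stacking machinery can treat them interchangeably:

- time-series learners (``arima``, ``ets``, ``stlm``, ``structts``) are
  fitted on the demand column alone and forecast h steps past the
  training origin;
- machine-learning learners (``lm``, ``glmnet``, ``rf``, ``gbm``,
  ``knn``) are fitted on the full model matrix and score a single
  feature row (direct, not recursive, multi-day forecasting).

Estimation itself is delegated: statsmodels for the state-space and
smoothing models, scikit-learn for the regressors. The bespoke content
is the contract, the hyperparameter grids and the blindness guarantees
around them. Negative point forecasts are clamped to zero (counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import DAYS_OF_WEEK, MONTHS, feature_columns
from .series import ValidationError

TIME_SERIES_LEARNERS = ("arima", "ets", "stlm", "structts")
ML_LEARNERS = ("lm", "glmnet", "rf", "gbm", "knn")
LEARNER_NAMES = TIME_SERIES_LEARNERS + ML_LEARNERS

#: learners that consume integer category codes instead of one-hot dummies
_TREE_LEARNERS = ("rf", "gbm")
#: learners whose features are standardized before fitting
_SCALED_LEARNERS = ("glmnet", "knn")


class FitFailure(RuntimeError):
    """A learner could not be fitted on this window; callers record and skip."""


class ContractError(ValueError):
    """fit/predict called outside the adapter contract."""


def default_grid(name: str) -> list[dict]:
    """Declared default hyperparameter grids (the source gives none)."""
    if name == "arima":
        return [{"order": (2, 1, 1), "seasonal_order": (1, 0, 0, 7)}]
    if name == "ets":
        return [{"trend": t, "seasonal": "add"} for t in (None, "add")]
    if name == "stlm":
        return [{"trend": t} for t in (None, "add")]
    if name == "structts":
        return [{"level": lv} for lv in ("llevel", "lltrend")]
    if name == "lm":
        return [{}]
    if name == "glmnet":
        return [
            {"mixture": m, "penalty": p}
            for m in (0.0, 0.5, 1.0)
            for p in np.logspace(-4, 1, 20)
        ]
    if name == "rf":
        return [{"max_features": mf, "n_trees": 500} for mf in (0.333, "sqrt", 1.0)]
    if name == "gbm":
        return [
            {"n_trees": n, "depth": d, "learning_rate": lr}
            for n in (100, 300)
            for d in (1, 3)
            for lr in (0.05, 0.1)
        ]
    if name == "knn":
        return [{"k": k} for k in (3, 5, 7, 9, 15)]
    raise ValidationError(f"unknown learner name {name!r}")


def complexity_key(name: str, hyperparams: Mapping[str, Any]) -> tuple:
    """Ordering used to break selection ties toward the simplest setting
    (fewest trees/neighbours, largest penalty, fewest model components)."""
    if name == "glmnet":
        return (-hyperparams.get("penalty", 0.0), hyperparams.get("mixture", 0.0))
    if name in ("rf", "gbm"):
        return (
            hyperparams.get("n_trees", 0),
            hyperparams.get("depth", 0),
            hyperparams.get("learning_rate", 0.0),
        )
    if name == "knn":
        return (hyperparams.get("k", 0),)
    return (len(hyperparams),)


@dataclass(frozen=True)
class LearnerSpec:
    """A named learner plus its hyperparameter grid."""

    name: str
    grid: Sequence[Mapping[str, Any]] = field(default=None)

    def __post_init__(self):
        if self.name not in LEARNER_NAMES:
            raise ValidationError(
                f"unknown learner name {self.name!r}; expected one of {LEARNER_NAMES}"
            )
        grid = self.grid if self.grid is not None else default_grid(self.name)
        grid = [dict(g) for g in grid]
        if not grid:
            raise ValidationError("grid must be non-empty")
        if self.name == "lm" and (len(grid) != 1 or grid[0]):
            raise ValidationError("lm's grid is exactly one empty setting")
        object.__setattr__(self, "grid", tuple(tuple(sorted(g.items())) for g in grid))

    @property
    def family(self) -> str:
        return "time_series" if self.name in TIME_SERIES_LEARNERS else "ml"

    @property
    def settings(self) -> list[dict]:
        return [dict(g) for g in self.grid]


def default_spec(name: str) -> LearnerSpec:
    return LearnerSpec(name, default_grid(name))


@dataclass
class FittedLearner:
    """A fitted forecaster bound to its training origin."""

    spec: LearnerSpec
    hyperparams: dict
    origin: pd.Timestamp
    horizon: int
    _state: Any = field(repr=False)
    _train_range: tuple[float, float] = field(repr=False, default=(0.0, np.inf))

    @property
    def family(self) -> str:
        return self.spec.family

    def predict(self, row: pd.DataFrame | None = None, horizon: int | None = None) -> float:
        return predict(self, row, horizon=horizon)


# ---------------------------------------------------------------------------
# feature encoding for the ML family


def encode_features(matrix: pd.DataFrame, learner: str) -> np.ndarray:
    """Encode a model-matrix slice into a numeric design.

    Month and day-of-week enter linear/kernel learners as one-hot
    indicators with January/Monday as the reference level; tree
    learners consume integer category codes. The matrix itself always
    stores categories — the adapter decides.
    """
    cols = feature_columns(matrix)
    parts = []
    for col in cols:
        s = matrix[col]
        if col == "month":
            parts.append(_encode_cat(s, MONTHS, learner, col))
        elif col == "day_of_week":
            parts.append(_encode_cat(s, DAYS_OF_WEEK, learner, col))
        else:
            parts.append(s.to_numpy(dtype=float).reshape(-1, 1))
    return np.hstack(parts)


def encoded_feature_names(matrix: pd.DataFrame, learner: str) -> list[str]:
    names: list[str] = []
    for col in feature_columns(matrix):
        if col in ("month", "day_of_week"):
            levels = MONTHS if col == "month" else DAYS_OF_WEEK
            if learner in _TREE_LEARNERS:
                names.append(col)
            else:
                names.extend(f"{col}[{lv}]" for lv in levels[1:])
        else:
            names.append(col)
    return names


def _encode_cat(s: pd.Series, levels, learner: str, col: str) -> np.ndarray:
    codes = pd.Categorical(s, categories=levels).codes.astype(float)
    if (codes < 0).any():
        raise ValidationError(f"{col}: value outside declared categories")
    if learner in _TREE_LEARNERS:
        return codes.reshape(-1, 1)
    return (codes.reshape(-1, 1) == np.arange(1, len(levels))).astype(float)


# ---------------------------------------------------------------------------
# fitting


def fit(
    spec: LearnerSpec,
    hyperparams: Mapping[str, Any],
    training_rows: pd.DataFrame,
    seed: int = 0,
) -> FittedLearner:
    """Fit one learner with one hyperparameter setting on a training window.

    ``training_rows`` is a contiguous slice of the model matrix; the
    time-series family uses only its demand column. Estimation failures
    raise :class:`FitFailure` for the caller to record and skip.
    """
    hyperparams = dict(hyperparams)
    if tuple(sorted(hyperparams.items())) not in spec.grid:
        raise ContractError(f"hyperparams {hyperparams} not in {spec.name}'s grid")
    rows = training_rows.dropna(subset=["demand"])
    if len(rows) < 3:
        raise FitFailure(f"{spec.name}: training window too short ({len(rows)} rows)")
    if not (rows["date"].diff().dropna() == pd.Timedelta(days=1)).all():
        raise ContractError("training rows must be contiguous in time")
    y = rows["demand"].to_numpy(dtype=float)
    origin = pd.Timestamp(rows["date"].iloc[-1])
    horizon = int(rows["horizon"].iloc[0])
    train_range = (float(y.min()), float(y.max()))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if spec.family == "time_series":
                state = _fit_time_series(spec.name, hyperparams, y)
            else:
                state = _fit_ml(spec.name, hyperparams, rows, y, seed)
    except (FitFailure, ContractError):
        raise
    except Exception as exc:
        raise FitFailure(f"{spec.name}{hyperparams}: {exc}") from exc
    return FittedLearner(spec, hyperparams, origin, horizon, state, train_range)


def _fit_time_series(name: str, hp: Mapping[str, Any], y: np.ndarray):
    if np.ptp(y) == 0.0:
        # degenerate constant window: every mean-reverting specification
        # forecasts the constant; avoid zero-variance estimation failures
        return ("constant", float(y[0]))
    if name == "arima":
        from statsmodels.tsa.arima.model import ARIMA

        res = ARIMA(
            y,
            order=tuple(hp.get("order", (2, 1, 1))),
            seasonal_order=tuple(hp.get("seasonal_order", (0, 0, 0, 0))),
        ).fit()
        return ("forecaster", res)
    if name == "ets":
        from statsmodels.tsa.holtwinters import ExponentialSmoothing

        res = ExponentialSmoothing(
            y,
            trend=hp.get("trend"),
            seasonal=hp.get("seasonal", "add"),
            seasonal_periods=7,
            initialization_method="estimated",
        ).fit()
        return ("forecaster", res)
    if name == "stlm":
        from statsmodels.tsa.holtwinters import ExponentialSmoothing
        from statsmodels.tsa.seasonal import STL

        stl = STL(pd.Series(y), period=7).fit()
        deseason = y - stl.seasonal.to_numpy()
        res = ExponentialSmoothing(
            deseason, trend=hp.get("trend"), initialization_method="estimated"
        ).fit()
        return ("stlm", (res, stl.seasonal.to_numpy()[-7:]))
    if name == "structts":
        from statsmodels.tsa.statespace.structural import UnobservedComponents

        res = UnobservedComponents(
            y, level=hp.get("level", "llevel"), seasonal=7
        ).fit(disp=False)
        return ("forecaster", res)
    raise ValidationError(f"unknown time-series learner {name!r}")


def _fit_ml(name: str, hp: Mapping[str, Any], rows: pd.DataFrame, y, seed: int):
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.linear_model import ElasticNet, LinearRegression
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    X = encode_features(rows, name)
    if name == "lm":
        est = LinearRegression()
    elif name == "glmnet":
        penalty = float(hp.get("penalty", 0.01))
        if penalty == 0.0:
            inner = LinearRegression()
        else:
            inner = ElasticNet(
                alpha=penalty, l1_ratio=float(hp.get("mixture", 0.5)), max_iter=5000
            )
        est = make_pipeline(StandardScaler(), inner)
    elif name == "rf":
        est = RandomForestRegressor(
            n_estimators=int(hp.get("n_trees", 500)),
            max_features=hp.get("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
    elif name == "gbm":
        est = GradientBoostingRegressor(
            n_estimators=int(hp.get("n_trees", 100)),
            max_depth=int(hp.get("depth", 3)),
            learning_rate=float(hp.get("learning_rate", 0.1)),
            random_state=seed,
        )
    elif name == "knn":
        k = int(hp.get("k", 5))
        if k > len(rows):
            raise FitFailure(f"knn: k={k} exceeds {len(rows)} training rows")
        est = make_pipeline(StandardScaler(), KNeighborsRegressor(n_neighbors=k))
    else:
        raise ValidationError(f"unknown ml learner {name!r}")
    est.fit(X, y)
    return ("ml", est)


# ---------------------------------------------------------------------------
# prediction


def predict(
    fitted: FittedLearner,
    row: pd.DataFrame | None = None,
    *,
    horizon: int | None = None,
) -> float:
    """Point forecast (patients, clamped at 0).

    Time-series learners forecast ``horizon`` steps past their training
    origin (the horizon may also be inferred from a target row's date).
    ML learners require the feature row of the target date.
    """
    if fitted.family == "time_series":
        if horizon is None:
            if row is None:
                raise ContractError("time-series predict needs a horizon or target row")
            horizon = int((pd.Timestamp(row["date"].iloc[0]) - fitted.origin).days)
        if horizon < 1:
            raise ContractError(f"horizon must be >= 1, got {horizon}")
        value = _predict_time_series(fitted._state, int(horizon))
    else:
        if row is None:
            raise ContractError(f"{fitted.spec.name} predict needs a target feature row")
        if len(row) != 1:
            raise ContractError("predict scores exactly one target row")
        kind, est = fitted._state
        X = encode_features(row, fitted.spec.name)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value = float(est.predict(X)[0])
    if not np.isfinite(value):
        raise FitFailure(f"{fitted.spec.name}: non-finite forecast")
    return max(0.0, float(value))


def _predict_time_series(state, h: int) -> float:
    kind, payload = state
    if kind == "constant":
        return payload
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if kind == "forecaster":
            return float(np.asarray(payload.forecast(h))[-1])
        if kind == "stlm":
            res, last_cycle = payload
            seasonal = last_cycle[(h - 1) % 7]
            return float(np.asarray(res.forecast(h))[-1] + seasonal)
    raise ValidationError(f"unknown fitted state {kind!r}")
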