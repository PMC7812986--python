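"""Convex-combination stacked regression.

A linear stacker over K base forecasters with weights constrained to
the probability simplex (w >= 0, sum w = 1), fitted by least squares on
held-out cross-validation predictions:

    minimize  || P w - y ||^2   subject to  w >= 0,  1'w = 1

The simplex constraint guarantees the ensemble forecast always lies
within the componentwise range of the base forecasts, and makes every
single learner a feasible vertex — so in-sample the stack can never be
worse than the best base learner. The program is a convex QP solved
with SLSQP from a uniform start to tight tolerance; an optional ridge
term on the weights gives the penalized variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .series import ValidationError


class StackError(ValidationError):
    pass


@dataclass(frozen=True)
class StackWeights:
    """Nonnegative, sum-to-one weights over learners."""

    weights: Mapping[str, float]
    n_rows_used: int = 0
    n_rows_dropped: int = 0
    objective: float = float("nan")
    ridge: float = 0.0

    def __post_init__(self):
        w = {k: float(v) for k, v in self.weights.items()}
        if not w:
            raise StackError("weights must be non-empty")
        if any(v < -1e-9 for v in w.values()):
            raise StackError("weights must be nonnegative")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise StackError("weights must sum to 1")
        object.__setattr__(self, "weights", dict(w))

    def __getitem__(self, name: str) -> float:
        return self.weights[name]

    @property
    def learners(self) -> list[str]:
        return list(self.weights)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, name="weight")


def fit_stack(
    cv_predictions: pd.DataFrame,
    actuals,
    ridge: float = 0.0,
) -> StackWeights:
    """Fit simplex-constrained least-squares weights.

    Parameters
    ----------
    cv_predictions : DataFrame, one column per learner
        Held-out (cross-validation) predictions, row-aligned with
        ``actuals``. Rows containing any missing prediction are dropped
        and counted.
    actuals : array-like
        Observed demand for the same rows.
    ridge : float
        Optional l2 penalty on the weights (the penalized variant).
    """
    if not isinstance(cv_predictions, pd.DataFrame):
        cv_predictions = pd.DataFrame(np.asarray(cv_predictions))
    if cv_predictions.shape[1] < 1 or len(cv_predictions) == 0:
        raise StackError("need at least one learner and one row of predictions")
    y = np.asarray(actuals, dtype=float)
    if len(y) != len(cv_predictions):
        raise StackError("predictions and actuals must have equal length")
    keep = cv_predictions.notna().all(axis=1) & np.isfinite(y)
    dropped = int((~keep).sum())
    P = cv_predictions.loc[keep].to_numpy(dtype=float)
    y = y[keep.to_numpy()]
    if len(P) == 0:
        raise StackError("no complete prediction rows to fit on")
    names = [str(c) for c in cv_predictions.columns]
    K = len(names)
    if K == 1:
        return StackWeights({names[0]: 1.0}, len(P), dropped, float(np.sum((P[:, 0] - y) ** 2)))

    PtP = P.T @ P + ridge * np.eye(K)
    Pty = P.T @ y

    def objective(w):
        return float(w @ PtP @ w - 2.0 * Pty @ w + y @ y)

    def gradient(w):
        return 2.0 * (PtP @ w - Pty)

    w0 = np.full(K, 1.0 / K)
    res = minimize(
        objective,
        w0,
        jac=gradient,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(K)}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    # polish: tiny weights that do not improve the fit are zeroed
    w[w < 1e-12] = 0.0
    w /= w.sum()
    obj = float(np.sum((P @ w - y) ** 2))
    return StackWeights(dict(zip(names, w)), len(P), dropped, obj, ridge)


def predict_stack(weights: StackWeights, predictions: Mapping[str, float]) -> float:
    """Weighted-average ensemble forecast for one date.

    Every positively weighted learner must supply a finite prediction;
    the result lies within [min, max] of the inputs used.
    """
    total = 0.0
    for name, w in weights.weights.items():
        if w == 0.0:
            continue
        if name not in predictions or not np.isfinite(predictions[name]):
            raise StackError(f"missing prediction for positively weighted learner {name!r}")
        total += w * float(predictions[name])
    return total


def stack_log(
    weights: StackWeights, prediction_table: pd.DataFrame, actuals: pd.Series
) -> pd.DataFrame:
    """Apply the stack across a date-indexed prediction table, returning a
    forecast log for the ensemble."""
    rows = []
    for date, row in prediction_table.iterrows():
        preds = row.dropna().to_dict()
        try:
            pred = predict_stack(weights, preds)
        except StackError:
            continue
        actual = float(actuals.loc[date])
        rows.append(
            {
                "target_date": date,
                "horizon": np.nan,
                "learner": "stack",
                "hyperparam_id": 0,
                "params": repr(weights.weights),
                "prediction": pred,
                "actual": actual,
                "absolute_error": abs(pred - actual),
                "status": "ok",
                "reason": "",
            }
        )
    return pd.DataFrame(rows)
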