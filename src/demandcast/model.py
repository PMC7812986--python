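"""High-level Model/Results interface.

:class:`DemandForecaster` is the model object: a demand series, its
covariate calendar and the run options (horizon, learner zoo, tuning
method, split geometry). ``fit()`` executes the full procedure —
validation backtests, hyperparameter selection over the test block,
convex stacking — and returns a :class:`ForecastResults` carrying the
forecast logs, the error scoreboard, the stack weights and a
``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .evaluation import mae, mape, permutation_importance, scoreboard
from .features import build_model_matrix
from .learners import LearnerSpec, default_spec, fit as fit_learner
from .series import CovariateCalendar, DemandSeries, ValidationError
from .stacking import StackWeights, fit_stack, stack_log
from .temporal_cv import make_split_plan, run_backtest
from .tuning import (
    RefitSchedule,
    SelectionRule,
    ValidationErrorPanel,
    run_batch_method,
    run_online_method,
    select_hyperparams,
)

DEFAULT_LEARNERS = ("ets", "stlm", "lm", "glmnet", "rf", "gbm", "knn")


class DemandForecaster:
    """Daily ED-demand forecasting model.

    Parameters
    ----------
    series, calendar : DemandSeries, CovariateCalendar
        Aligned daily attendance counts and covariates.
    horizon : {1, 3, 7}
        Days ahead to forecast.
    learners : sequence of LearnerSpec or learner names
        The zoo; defaults to a balanced mix of both families.
    method : {"batch", "online"}
        Hyperparameter regime over the test block.
    rule : SelectionRule
        Batch selection rule (ignored for online).
    period : int
        Online refit period in days (ignored for batch).
    train_length, val_length, test_length : int
        Split geometry in days (train window / validation block /
        test block), scaled-down analogue of 1460/730/730.
    stack : bool
        Fit the convex stacker on validation-block predictions.
    ridge : float
        Optional l2 penalty on stack weights.
    seed : int
        Root seed; per-stage seeds are derived from it.
    """

    def __init__(
        self,
        series: DemandSeries,
        calendar: CovariateCalendar,
        horizon: int = 1,
        learners: Sequence = DEFAULT_LEARNERS,
        method: str = "batch",
        rule: SelectionRule | None = None,
        period: int = 7,
        train_length: int = 1460,
        val_length: int = 730,
        test_length: int = 730,
        stack: bool = True,
        ridge: float = 0.0,
        seed: int = 0,
    ):
        if not calendar.aligned_with(series):
            raise ValidationError("calendar and series must cover the same span")
        if method not in ("batch", "online"):
            raise ValidationError("method must be 'batch' or 'online'")
        self.series = series
        self.calendar = calendar
        self.horizon = int(horizon)
        self.specs = [
            s if isinstance(s, LearnerSpec) else default_spec(s) for s in learners
        ]
        self.method = method
        self.rule = rule if rule is not None else SelectionRule("validation_average")
        self.period = int(period)
        self.train_length = int(train_length)
        self.val_length = int(val_length)
        self.test_length = int(test_length)
        self.stack = bool(stack)
        self.ridge = float(ridge)
        self.seed = int(seed)

    @classmethod
    def from_csv(cls, series_path, calendar_path, **kwargs) -> "DemandForecaster":
        return cls(
            DemandSeries.from_csv(series_path),
            CovariateCalendar.from_csv(calendar_path),
            **kwargs,
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int | None = None) -> "ForecastResults":
        seed = self.seed if seed is None else int(seed)
        n = len(self.series)
        matrix = build_model_matrix(self.series, self.calendar, self.horizon)
        val_logs: dict[str, pd.DataFrame] = {}
        test_logs: dict[str, pd.DataFrame] = {}
        traces: dict[str, pd.DataFrame] = {}
        chosen_ids: dict[str, int] = {}
        for i, spec in enumerate(self.specs):
            stage_seed = (seed + 1009 * i) % (2**31 - 1)
            # validation backtest over the val block, all grid settings
            val_plan = make_split_plan(
                n - self.test_length,
                self.val_length,
                self.horizon,
                self.train_length,
                start_date=self.series.start_date,
            )
            val_log = run_backtest(val_plan, spec, matrix, seed=stage_seed)
            val_logs[spec.name] = val_log
            panel = ValidationErrorPanel.from_log(val_log)
            chosen_ids[spec.name] = select_hyperparams(
                panel,
                SelectionRule("validation_average"),
                self.series.end_date + pd.Timedelta(days=1),
                spec,
            )
            if self.method == "batch":
                log, trace = run_batch_method(
                    self.series, self.calendar, spec, self.rule, self.horizon,
                    self.train_length, self.val_length, self.test_length,
                    seed=stage_seed,
                )
                log = log.assign(method="batch", rule=self.rule.kind)
            else:
                log, trace = run_online_method(
                    self.series, self.calendar, spec, RefitSchedule(self.period),
                    self.horizon, self.train_length, self.val_length,
                    self.test_length, seed=stage_seed,
                )
                log = log.assign(method="online", period=self.period)
            test_logs[spec.name] = log
            traces[spec.name] = trace

        weights, ens_log = None, None
        if self.stack and len(self.specs) > 1:
            weights, ens_log = self._fit_stacker(val_logs, test_logs, chosen_ids)
        return ForecastResults(self, val_logs, test_logs, traces, weights, ens_log, seed)

    def _fit_stacker(self, val_logs, test_logs, chosen_ids):
        # one column per learner: validation predictions generated by the
        # same selection process that produces its test predictions —
        # daily rule-based re-selection for batch (first day has no prior
        # errors and is dropped), the panel-average setting for online
        cols = {}
        for name, log in val_logs.items():
            ok = log[log["status"] == "ok"]
            if self.method == "batch":
                spec = next(s for s in self.specs if s.name == name)
                panel = ValidationErrorPanel.from_log(log)
                picks = {}
                for date in panel.frame.index[1:]:
                    hp_id = select_hyperparams(panel, self.rule, date, spec)
                    picks[date] = hp_id
                sel = pd.Series(picks)
                merged = ok.set_index(["target_date", "hyperparam_id"])["prediction"]
                cols[name] = pd.Series(
                    {d: merged.get((d, hp)) for d, hp in sel.items()}
                ).dropna()
            else:
                chosen = ok[ok["hyperparam_id"] == chosen_ids[name]]
                cols[name] = chosen.set_index("target_date")["prediction"]
        table = pd.DataFrame(cols).dropna()
        if table.empty:
            return None, None
        actual_src = next(iter(val_logs.values()))
        actuals = (
            actual_src.drop_duplicates("target_date")
            .set_index("target_date")["actual"]
            .loc[table.index]
        )
        weights = fit_stack(table, actuals, ridge=self.ridge)
        # apply on the untouched test block
        test_cols = {
            name: log[log["status"] == "ok"].set_index("target_date")["prediction"]
            for name, log in test_logs.items()
        }
        test_table = pd.DataFrame(test_cols).dropna()
        test_actuals = (
            next(iter(test_logs.values()))
            .drop_duplicates("target_date")
            .set_index("target_date")["actual"]
            .loc[test_table.index]
        )
        ens_log = stack_log(weights, test_table, test_actuals)
        ens_log["horizon"] = self.horizon
        return weights, ens_log

    # -- metadata ----------------------------------------------------------

    def config_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "learners": [
                {"name": s.name, "grid": s.settings} for s in self.specs
            ],
            "method": self.method,
            "rule": {"kind": self.rule.kind, "n": self.rule.n, "alpha": self.rule.alpha},
            "period": self.period,
            "train_length": self.train_length,
            "val_length": self.val_length,
            "test_length": self.test_length,
            "stack": self.stack,
            "ridge": self.ridge,
            "seed": self.seed,
            "negative_forecast_clamp": 0.0,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.config_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ForecastResults:
    """Fitted-run artifacts: logs, weights, scores and a summary table."""

    model: DemandForecaster
    val_logs: Mapping[str, pd.DataFrame]
    test_logs: Mapping[str, pd.DataFrame]
    traces: Mapping[str, pd.DataFrame]
    stack_weights: StackWeights | None
    stack_log: pd.DataFrame | None = None
    seed: int = 0
    _scoreboard: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self):
        logs = list(self.test_logs.values())
        if self.stack_log is not None and len(self.stack_log):
            logs = logs + [self.stack_log]
        object.__setattr__(self, "_scoreboard", scoreboard(logs))

    @property
    def scoreboard(self) -> pd.DataFrame:
        return self._scoreboard

    def log_for(self, learner: str) -> pd.DataFrame:
        if learner == "stack":
            return self.stack_log
        return self.test_logs[learner]

    def mae(self, learner: str) -> float:
        log = self.log_for(learner)
        ok = log[log["status"] == "ok"]
        return mae(ok["actual"], ok["prediction"])

    def mape(self, learner: str) -> float:
        log = self.log_for(learner)
        ok = log[log["status"] == "ok"]
        return mape(ok["actual"], ok["prediction"])

    def importance(self, learner: str, repeats: int = 10) -> pd.DataFrame:
        """Permutation importance of an ML learner's selected setting,
        computed on the test-block rows of the model matrix."""
        m = self.model
        spec = next(s for s in m.specs if s.name == learner)
        trace = self.traces[learner]
        hp_id = int(trace["hyperparam_id"].iloc[-1])
        matrix = build_model_matrix(m.series, m.calendar, m.horizon)
        n = len(m.series)
        test_start = m.series.start_date + pd.Timedelta(days=n - m.test_length)
        origin = test_start - pd.Timedelta(days=m.horizon)
        train_rows = matrix[
            (matrix["date"] > origin - pd.Timedelta(days=m.train_length))
            & (matrix["date"] <= origin)
        ]
        fitted = fit_learner(spec, spec.settings[hp_id], train_rows, seed=self.seed)
        held_out = matrix[matrix["date"] >= test_start]
        return permutation_importance(fitted, held_out, repeats=repeats, seed=self.seed)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Demand forecasting results",
            "=" * 60,
            f"span: {m.series.start_date.date()} .. {m.series.end_date.date()}"
            f"  ({len(m.series)} days)",
            f"horizon: {m.horizon} day(s)   method: {m.method}"
            + (f" (rule={m.rule.kind})" if m.method == "batch" else f" (period={m.period}d)"),
            f"geometry: train {m.train_length} / validation {m.val_length}"
            f" / test {m.test_length} days",
            f"seed: {self.seed}   config: {m.config_hash()}",
            "",
            "Scoreboard (sorted by MAE, patients):",
            self.scoreboard.to_string(index=False, float_format=lambda v: f"{v:.2f}"),
        ]
        if self.stack_weights is not None:
            lines += [
                "",
                "Stack weights (convex combination):",
                self.stack_weights.as_series().to_string(float_format=lambda v: f"{v:.3f}"),
            ]
        return "\n".join(lines)
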