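import math

import numpy as np
import pandas as pd
import pytest

from demandcast import (
    RefitSchedule,
    SelectionRule,
    ValidationErrorPanel,
    run_batch_method,
    run_online_method,
    select_hyperparams,
)
from demandcast.learners import LearnerSpec
from demandcast.series import ValidationError
from demandcast.tuning import SelectionError

GLMNET_SMALL = LearnerSpec(
    "glmnet", [{"mixture": 0.5, "penalty": p} for p in (0.01, 0.1, 1.0)]
)


def panel_from(dates, columns):
    frame = pd.DataFrame(columns, index=pd.to_datetime(dates))
    return ValidationErrorPanel(frame)


@pytest.fixture
def three_day_panel():
    return panel_from(
        ["2020-01-01", "2020-01-02", "2020-01-03"],
        {0: [5.0, 5.0, 1.0], 1: [2.0, 2.0, 4.0]},
    )


class TestRuleValidation:
    def test_unknown_kind(self):
        with pytest.raises(ValidationError):
            SelectionRule("best_ever")

    @pytest.mark.parametrize("kw", [{"n": 0}, {"alpha": 0.0}, {"alpha": 1.5}])
    def test_parameter_ranges(self, kw):
        with pytest.raises(ValidationError):
            SelectionRule("ema", **kw)


class TestSelection:
    AS_OF = "2020-01-04"

    def test_hand_worked_example(self, three_day_panel):
        # A = (5,5,1), B = (2,2,4): previous day favours A, average favours B
        assert select_hyperparams(three_day_panel, SelectionRule("previous_day"), self.AS_OF) == 0
        assert (
            select_hyperparams(three_day_panel, SelectionRule("validation_average"), self.AS_OF)
            == 1
        )

    def test_single_setting_grid_every_rule(self):
        panel = panel_from(["2020-01-01", "2020-01-02"], {0: [3.0, 9.0]})
        for kind in ("previous_day", "past_n_days", "ema", "validation_average",
                     "default_resample"):
            assert select_hyperparams(panel, SelectionRule(kind), self.AS_OF) == 0

    def test_ema_alpha_one_is_previous_day(self, three_day_panel):
        assert select_hyperparams(
            three_day_panel, SelectionRule("ema", alpha=1.0), self.AS_OF
        ) == select_hyperparams(three_day_panel, SelectionRule("previous_day"), self.AS_OF)

    def test_past_n_full_panel_is_validation_average(self, three_day_panel):
        assert select_hyperparams(
            three_day_panel, SelectionRule("past_n_days", n=3), self.AS_OF
        ) == select_hyperparams(
            three_day_panel, SelectionRule("validation_average"), self.AS_OF
        )

    def test_limiting_equivalences_on_random_panels(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n_days, n_settings = rng.integers(2, 15), rng.integers(2, 6)
            panel = panel_from(
                pd.date_range("2020-01-01", periods=n_days),
                {j: rng.exponential(10, n_days) for j in range(n_settings)},
            )
            as_of = "2020-02-01"
            assert select_hyperparams(panel, SelectionRule("ema", alpha=1.0), as_of) == \
                select_hyperparams(panel, SelectionRule("previous_day"), as_of)
            assert select_hyperparams(panel, SelectionRule("past_n_days", n=n_days), as_of) == \
                select_hyperparams(panel, SelectionRule("validation_average"), as_of)

    def test_only_information_before_as_of(self, three_day_panel):
        """Rule criteria are blind to errors at or after the prediction day."""
        tampered = three_day_panel.frame.copy()
        tampered.loc[pd.Timestamp("2020-01-03")] = [0.0, 100.0]
        for kind in ("previous_day", "ema", "past_n_days", "validation_average"):
            rule = SelectionRule(kind, n=2)
            assert select_hyperparams(three_day_panel, rule, "2020-01-03") == \
                select_hyperparams(ValidationErrorPanel(tampered), rule, "2020-01-03")

    def test_empty_panel_is_selection_error(self, three_day_panel):
        with pytest.raises(SelectionError):
            select_hyperparams(three_day_panel, SelectionRule("previous_day"), "2019-01-01")

    def test_tie_breaks_toward_lowest_id_then_complexity(self):
        panel = panel_from(["2020-01-01"], {0: [2.0], 1: [2.0]})
        assert select_hyperparams(panel, SelectionRule("validation_average"), self.AS_OF) == 0
        # caret-style rule prefers the least complex setting: largest penalty
        spec = GLMNET_SMALL
        panel3 = panel_from(["2020-01-01"], {0: [2.0], 1: [2.0], 2: [2.0]})
        assert (
            select_hyperparams(panel3, SelectionRule("default_resample"), self.AS_OF, spec)
            == 2
        )


class TestBatchMethod:
    def test_scaled_geometry_logs_one_record_per_day(self, small_world):
        _, series, calendar = small_world
        log, trace = run_batch_method(
            series, calendar, GLMNET_SMALL, SelectionRule("past_n_days", n=7),
            horizon=1, train_length=120, val_length=60, test_length=30, seed=1,
        )
        assert len(log) == 30
        assert len(trace) == 30
        assert log["target_date"].is_unique

    def test_noise_free_stationary_selection_constant(self):
        from demandcast import SyntheticConfig, generate

        config = SyntheticConfig(
            n_days=240, dispersion=0.0, trend_slopes=(0.0,), trend_breakpoints=(),
            annual_amplitude=0.0, holiday_effect=0.0, event_effects={},
            weather_coupling=(0.0, 0.0, 0.0), flu_coupling=0.0, seed=5,
        )
        series, calendar = generate(config)
        log, trace = run_batch_method(
            series, calendar, GLMNET_SMALL, SelectionRule("validation_average"),
            horizon=1, train_length=100, val_length=40, test_length=10, seed=1,
        )
        assert trace["hyperparam_id"].nunique() == 1

    def test_infeasible_geometry(self, small_world):
        _, series, calendar = small_world
        from demandcast.temporal_cv import SizingError

        with pytest.raises(SizingError):
            run_batch_method(
                series, calendar, GLMNET_SMALL, SelectionRule("previous_day"),
                horizon=1, train_length=500, val_length=60, test_length=30,
            )


class TestOnlineMethod:
    @pytest.mark.parametrize("period,expected_events", [(30, 1), (1, 30), (7, 5)])
    def test_selection_event_count(self, small_world, period, expected_events):
        _, series, calendar = small_world
        log, trace = run_online_method(
            series, calendar, LearnerSpec("knn", [{"k": 5}, {"k": 9}]),
            RefitSchedule(period), horizon=1,
            train_length=120, val_length=30, test_length=30, seed=1,
        )
        assert len(trace) == expected_events == math.ceil(30 / period)
        assert len(log) == 30

    def test_online_period1_matches_batch_previous_day_selection(self, three_day_panel=None):
        """With a one-day lookback the online average criterion coincides
        with the batch previous-day rule on any shared panel."""
        rng = np.random.default_rng(42)
        dates = pd.date_range("2020-03-01", periods=10)
        panel = panel_from(dates, {j: rng.exponential(5, 10) for j in range(4)})
        for as_of in dates[1:]:
            one_day = ValidationErrorPanel(panel.frame[panel.frame.index == as_of - pd.Timedelta(days=1)])
            assert select_hyperparams(one_day, SelectionRule("validation_average"), as_of) \
                == select_hyperparams(panel, SelectionRule("previous_day"), as_of)
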