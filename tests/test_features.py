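import numpy as np
import pandas as pd
import pytest

from demandcast import DemandSeries, build_model_matrix, scaled_time_index
from demandcast.features import (
    AlignmentError,
    MATRIX_COLUMNS,
    UnsupportedHorizonError,
    matrix_from_csv,
    matrix_to_csv,
)
from demandcast.series import ValidationError

from conftest import flat_calendar


def row_for(matrix, date):
    hit = matrix[matrix["date"] == pd.Timestamp(date)]
    assert len(hit) == 1
    return hit.iloc[0]


class TestLagArithmetic:
    def test_horizon_1_next_day(self, toy_series, toy_calendar):
        matrix = build_model_matrix(toy_series, toy_calendar, 1)
        # day 15 is one past the 14-day series end
        row = row_for(matrix, toy_series.end_date + pd.Timedelta(days=1))
        assert row["yesterday"] == 14
        assert row["same_day_last_week"] == 8
        assert row["average_of_previous_week"] == pytest.approx(11.0)
        assert pd.isna(row["demand"])

    def test_horizon_7_origin_contract(self, toy_series, toy_calendar):
        matrix = build_model_matrix(toy_series, toy_calendar, 7)
        # target day 21: origin is day 14, the most recent observed day
        row = row_for(matrix, toy_series.start_date + pd.Timedelta(days=20))
        assert row["origin"] == toy_series.end_date
        assert row["yesterday"] == 14
        assert row["same_day_last_week"] == 14  # demand at target-7 = day 14
        assert row["average_of_previous_week"] == pytest.approx(11.0)

    def test_in_sample_row(self, toy_series, toy_calendar):
        matrix = build_model_matrix(toy_series, toy_calendar, 1)
        row = row_for(matrix, toy_series.start_date + pd.Timedelta(days=7))  # day 8
        assert row["demand"] == 8
        assert row["yesterday"] == 7
        assert row["same_day_last_week"] == 1
        assert row["average_of_previous_week"] == pytest.approx(4.0)


class TestSchema:
    def test_column_layout_and_types(self, small_matrix):
        """The emitted row layout mirrors the published model-matrix excerpt:
        demand, month, yesterday, same-day-last-week, weekly average, time,
        holiday flags, day of week, previous-day weather/flu, event flags."""
        cols = list(small_matrix.columns)
        assert cols[: len(MATRIX_COLUMNS)] == list(MATRIX_COLUMNS)
        assert {"carnival", "christmas"} <= set(cols)
        assert small_matrix["month"].dtype == "category"
        assert small_matrix["day_of_week"].dtype == "category"
        assert small_matrix["bank_holiday"].dtype == bool
        assert small_matrix["same_day_last_week"].dtype == float
        # a concrete spring Thursday behaves like the published excerpt row
        row = small_matrix[small_matrix["day_of_week"] == "Thursday"].iloc[0]
        assert row["month"] in (
            "January", "February", "March", "April", "May", "June", "July",
            "August", "September", "October", "November", "December",
        )
        assert isinstance(bool(row["bank_holiday"]), bool)
        assert row["yesterday"] >= 0 and row["average_of_previous_week"] >= 0

    def test_feature_cells_complete(self, small_matrix):
        features = small_matrix.drop(columns=["demand"])
        assert not features.isna().any().any()

    def test_csv_round_trip(self, small_matrix, tmp_path):
        path = tmp_path / "m.csv"
        matrix_to_csv(small_matrix, path)
        back = matrix_from_csv(path)
        assert list(back.columns) == list(small_matrix.columns)
        np.testing.assert_allclose(
            back["average_of_previous_week"], small_matrix["average_of_previous_week"]
        )
        assert (back["day_of_week"] == small_matrix["day_of_week"]).all()


class TestContracts:
    def test_unsupported_horizon(self, toy_series, toy_calendar):
        with pytest.raises(UnsupportedHorizonError):
            build_model_matrix(toy_series, toy_calendar, 2)

    def test_misaligned_calendar(self, toy_series):
        other = flat_calendar("2021-05-01", len(toy_series))
        with pytest.raises(AlignmentError):
            build_model_matrix(toy_series, other, 1)

    def test_too_short_series(self):
        short = DemandSeries("2020-01-06", np.arange(1, 6))
        with pytest.raises(ValidationError, match="short"):
            build_model_matrix(short, flat_calendar("2020-01-06", 5), 1)

    @pytest.mark.parametrize("horizon", [1, 3, 7])
    def test_no_leakage_under_corruption(self, small_world, horizon):
        """Features of a row depend only on counts dated <= its origin."""
        _, series, calendar = small_world
        matrix = build_model_matrix(series, calendar, horizon)
        probe = matrix.iloc[len(matrix) // 2]
        origin_offset = (probe["origin"] - series.start_date).days
        corrupted_counts = series.counts.copy()
        corrupted_counts[origin_offset + 1 :] = 1  # trash everything after origin
        corrupted = DemandSeries(series.start_date, corrupted_counts)
        rebuilt = build_model_matrix(corrupted, calendar, horizon)
        again = rebuilt[rebuilt["date"] == probe["date"]].iloc[0]
        for col in ("yesterday", "same_day_last_week", "average_of_previous_week"):
            assert again[col] == probe[col], col

    def test_horizon_eligibility_nested(self, small_world):
        _, series, calendar = small_world
        dates = {
            h: set(build_model_matrix(series, calendar, h, include_future=False)["date"])
            for h in (1, 7)
        }
        assert dates[7] <= dates[1]

    def test_rebuild_bit_identical(self, small_world):
        _, series, calendar = small_world
        m1 = build_model_matrix(series, calendar, 3)
        m2 = build_model_matrix(series, calendar, 3)
        pd.testing.assert_frame_equal(m1, m2)


class TestScaledTimeIndex:
    def test_midpoint_is_zero(self):
        assert scaled_time_index(11, 6) == pytest.approx(0.0)

    def test_endpoints_near_half(self):
        L = 100
        first, last = scaled_time_index(L, 1), scaled_time_index(L, L)
        assert first == pytest.approx(-0.5, abs=0.51 / L)
        assert last == pytest.approx(0.5, abs=0.51 / L)

    def test_step_is_inverse_window(self):
        L = 73
        pos = np.arange(1, L + 4)  # includes extrapolated forecast positions
        vals = scaled_time_index(L, pos)
        np.testing.assert_allclose(np.diff(vals), 1.0 / L)

    def test_strictly_increasing_and_validated(self):
        vals = scaled_time_index(10, np.arange(1, 11))
        assert (np.diff(vals) > 0).all()
        with pytest.raises(ValidationError):
            scaled_time_index(0, 1)
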