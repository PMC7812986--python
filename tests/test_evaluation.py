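import numpy as np
import pandas as pd
import pytest

from demandcast import (
    DemandSeries,
    SyntheticConfig,
    build_model_matrix,
    diagnostics,
    generate,
    mae,
    mape,
    permutation_importance,
    scoreboard,
)
from demandcast.learners import ContractError, LearnerSpec, fit
from demandcast.series import ValidationError

from conftest import flat_calendar


class TestPointMetrics:
    def test_identical_vectors_zero(self):
        assert mae([5, 8], [5, 8]) == 0.0
        assert mape([5, 8], [5, 8]) == 0.0

    def test_hand_examples(self):
        assert mae([100, 200], [110, 180]) == pytest.approx(15.0)
        assert mape([100, 200], [110, 180]) == pytest.approx(10.0)

    def test_mae_permutation_symmetry(self):
        a, p = np.array([3.0, 9.0, 4.0]), np.array([2.0, 11.0, 4.0])
        order = [2, 0, 1]
        assert mae(a, p) == pytest.approx(mae(a[order], p[order]))

    def test_mape_scale_invariance(self):
        a, p = np.array([100.0, 200.0]), np.array([110.0, 180.0])
        assert mape(a, p) == pytest.approx(mape(7.3 * a, 7.3 * p))

    def test_length_mismatch_and_zero_actual(self):
        with pytest.raises(ValidationError):
            mae([1, 2], [1])
        with pytest.raises(ValidationError, match="positive"):
            mape([0, 2], [1, 2])


def tiny_log(learner, errors, start="2020-01-01"):
    dates = pd.date_range(start, periods=len(errors))
    actual = np.full(len(errors), 100.0)
    return pd.DataFrame(
        {
            "target_date": dates,
            "horizon": 1,
            "learner": learner,
            "hyperparam_id": 0,
            "params": "{}",
            "prediction": actual + np.asarray(errors),
            "actual": actual,
            "absolute_error": np.abs(errors),
            "status": "ok",
            "reason": "",
        }
    )


class TestScoreboard:
    def test_single_record_echoes_error(self):
        board = scoreboard(tiny_log("lm", [5.0])[:1])
        assert board.loc[0, "mae"] == pytest.approx(5.0)
        assert board.loc[0, "n_records"] == 1

    def test_ordering_matches_hand_ranking(self):
        board = scoreboard([tiny_log("bad", [20, 20]), tiny_log("good", [1, 3])])
        assert list(board["learner"]) == ["good", "bad"]
        assert board.loc[0, "mae"] == pytest.approx(2.0)

    def test_merging_disjoint_logs_concatenates_reports(self):
        l1, l2 = tiny_log("a", [2, 4]), tiny_log("b", [6, 8], start="2020-02-01")
        merged = scoreboard([l1, l2])
        separate = pd.concat([scoreboard(l1), scoreboard(l2)], ignore_index=True)
        pd.testing.assert_frame_equal(merged, separate.sort_values("mae").reset_index(drop=True))

    def test_record_counts_conserved(self):
        log = tiny_log("a", [1, 2, 3])
        log.loc[2, "status"] = "skipped"
        board = scoreboard(log)
        assert board.loc[0, "n_records"] + board.loc[0, "n_skipped"] == 3

    def test_empty_log_warns(self):
        with pytest.warns(UserWarning):
            board = scoreboard(tiny_log("a", [])[0:0])
        assert board.empty


@pytest.fixture(scope="module")
def dominant_weekday_world():
    config = SyntheticConfig(
        n_days=400, seed=2,
        weekday_effects=(80.0, -40.0, 30.0, -20.0, 10.0, -60.0, 0.0),
        trend_slopes=(0.0,), trend_breakpoints=(), annual_amplitude=0.0,
        holiday_effect=0.0, event_effects={}, weather_coupling=(0.0, 0.0, 0.0),
        flu_coupling=0.0,
    )
    series, calendar = generate(config)
    matrix = build_model_matrix(series, calendar, 1).dropna(subset=["demand"])
    fitted = fit(LearnerSpec("lm"), {}, matrix.iloc[:300])
    return fitted, matrix.iloc[300:]


class TestPermutationImportance:
    def test_percentages_sum_to_100_and_reproducible(self, dominant_weekday_world):
        fitted, held = dominant_weekday_world
        r1 = permutation_importance(fitted, held, repeats=3, seed=9)
        r2 = permutation_importance(fitted, held, repeats=3, seed=9)
        assert r1["importance_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (r1["importance_pct"] >= 0).all()
        pd.testing.assert_frame_equal(r1, r2)

    def test_dominant_covariate_ranks_first(self, dominant_weekday_world):
        fitted, held = dominant_weekday_world
        report = permutation_importance(fitted, held, repeats=5, seed=0)
        assert report.loc[0, "feature"] == "day_of_week"
        assert report.loc[0, "importance_pct"] > 50

    def test_time_series_learner_rejected(self, small_world, small_matrix):
        obs = small_matrix.dropna(subset=["demand"])
        fitted = fit(LearnerSpec("ets", [{"trend": None, "seasonal": "add"}]),
                     {"trend": None, "seasonal": "add"}, obs.iloc[:100])
        with pytest.raises(ContractError):
            permutation_importance(fitted, obs.iloc[100:])

    def test_irrelevant_feature_near_zero(self, dominant_weekday_world):
        """Covariates the generator never couples in (e.g. precipitation)
        carry almost no importance for a fitted linear model."""
        fitted, held = dominant_weekday_world
        report = permutation_importance(fitted, held, repeats=5, seed=1)
        precip = report.set_index("feature").loc["precipitation_prev_day", "importance_pct"]
        assert precip < 5.0


class TestDiagnostics:
    def test_pure_weekly_cycle(self):
        cycle = np.array([220, 210, 205, 200, 195, 180, 170])
        series = DemandSeries("2020-01-06", np.tile(cycle, 12))
        d = diagnostics(series)
        # remainder vanishes and the weekday profile reproduces the cycle
        assert np.abs(d.remainder).max() < 1.0
        np.testing.assert_allclose(d.weekday_profile.to_numpy(), cycle, atol=0.5)
        assert d.weekday_profile.index[0] == "Monday"

    def test_additive_reconstruction_exact(self, small_world):
        _, series, _ = small_world
        d = diagnostics(series)
        np.testing.assert_allclose(
            d.reconstruction().to_numpy(), series.counts.astype(float), atol=1e-8
        )

    def test_acf_lag0_is_one_and_weekly_beats_lag3(self, small_world):
        _, series, _ = small_world
        d = diagnostics(series)
        assert d.acf[0] == pytest.approx(1.0)
        assert d.acf[7] > d.acf[3]

    def test_too_short_series_sizing_error(self):
        with pytest.raises(ValidationError, match="short"):
            diagnostics(DemandSeries("2020-01-06", np.arange(10) + 5))

    def test_plot_writes_figure(self, small_world, tmp_path):
        from demandcast.evaluation import plot_diagnostics

        _, series, _ = small_world
        out = tmp_path / "diag.png"
        plot_diagnostics(diagnostics(series), out)
        assert out.stat().st_size > 0
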