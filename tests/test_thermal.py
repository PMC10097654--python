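"""Baseline calibration, DHW accumulation and grid alignment."""

import numpy as np
import pandas as pd
import pytest

from coraltrade import thermal
from coraltrade.data_io import CATEGORY_WEIGHT
from coraltrade.errors import (DegenerateFitError, GapError,
                               InsufficientDataError)


def daily_log(tank, start, daily_temps, per_day=144):
    """Constant-temperature days sampled at 10-min cadence."""
    rows = []
    for d, temp in enumerate(daily_temps):
        times = pd.date_range(pd.Timestamp(start) + pd.Timedelta(days=d),
                              periods=per_day, freq=pd.Timedelta(days=1) / per_day)
        rows.append(pd.DataFrame({"tank_id": tank, "timestamp": times,
                                  "temp_c": float(temp)}))
    return pd.concat(rows, ignore_index=True)


BASE = thermal.ClimatologyBaseline(mmm=29.0, intercept=0.0, slope=1.0,
                                   mmm_adj=29.0)


class TestBaseline:
    def test_identity_calibration(self):
        dates = pd.date_range("2017-01-01", periods=60)
        s = pd.Series(np.linspace(27, 31, 60), index=dates)
        b = thermal.fit_baseline_adjustment(s, s, mmm=30.0)
        assert b.slope == pytest.approx(1.0)
        assert b.intercept == pytest.approx(0.0, abs=1e-12)
        assert b.mmm_adj == pytest.approx(30.0)

    def test_exact_affine_offset(self):
        dates = pd.date_range("2017-01-01", periods=90)
        sat = pd.Series(28 + np.sin(np.arange(90) / 10), index=dates)
        b = thermal.fit_baseline_adjustment(sat, sat + 0.7, mmm=29.5)
        assert b.mmm_adj == pytest.approx(29.5 + 0.7, abs=1e-9)

    def test_noisy_affine_recovery_within_2se(self):
        rng = np.random.default_rng(42)
        dates = pd.date_range("2017-01-01", periods=365)
        sat = pd.Series(28 + 1.5 * np.sin(np.arange(365) / 58), index=dates)
        situ = 0.4 + 1.05 * sat + rng.normal(0, 0.25, 365)
        b = thermal.fit_baseline_adjustment(sat, pd.Series(situ.to_numpy(),
                                                           index=dates), 29.0)
        se = 0.25 / (sat.std() * np.sqrt(365))
        assert abs(b.slope - 1.05) < 2 * se

    def test_too_few_overlapping_days(self):
        dates = pd.date_range("2017-01-01", periods=10)
        s = pd.Series(np.arange(10.0), index=dates)
        with pytest.raises(InsufficientDataError):
            thermal.fit_baseline_adjustment(s, s, 29.0)

    def test_zero_satellite_variance(self):
        dates = pd.date_range("2017-01-01", periods=60)
        flat = pd.Series(29.0, index=dates)
        with pytest.raises(DegenerateFitError):
            thermal.fit_baseline_adjustment(flat, flat + 0.5, 29.0)


class TestDhw:
    def test_constant_anomaly_closed_form(self):
        # 10 baseline days then 28 days at +2 degC: DHW = 2*28/7 = 8.0
        log = daily_log("T2", "2018-08-01", [29.0] * 10 + [31.0] * 28)
        dhw = thermal.compute_dhw(log, BASE)
        assert dhw["dhw_c_weeks"].iloc[-1] == pytest.approx(8.0, abs=1e-12)

    def test_small_anomaly_never_accumulates(self):
        log = daily_log("T2", "2018-08-01", [29.5] * 40)
        dhw = thermal.compute_dhw(log, BASE)
        assert (dhw["dhw_c_weeks"] == 0).all()

    def test_boundary_anomaly_strict_rule(self):
        log = daily_log("T2", "2018-08-01", [30.0] * 40)  # anomaly exactly 1.0
        assert (thermal.compute_dhw(log, BASE)["dhw_c_weeks"] == 0).all()
        inclusive = thermal.compute_dhw(log, BASE, hotspot_rule=">=1")
        assert inclusive["dhw_c_weeks"].iloc[-1] == pytest.approx(40 / 7)

    def test_cadence_invariance(self):
        temps = [29.0] * 5 + [31.5] * 20
        fine = thermal.compute_dhw(daily_log("T2", "2018-08-01", temps, 144), BASE)
        coarse = thermal.compute_dhw(daily_log("T2", "2018-08-01", temps, 24), BASE)
        np.testing.assert_allclose(fine["dhw_c_weeks"], coarse["dhw_c_weeks"])

    def test_matches_brute_force_window_sum(self):
        rng = np.random.default_rng(7)
        anomalies = rng.uniform(0, 3, 120)
        log = daily_log("T2", "2018-01-01", 29.0 + anomalies)
        dhw = thermal.compute_dhw(log, BASE)["dhw_c_weeks"].to_numpy()
        hot = np.where(anomalies > 1.0, anomalies, 0.0)
        expected = [hot[max(0, t - 83):t + 1].sum() / 7 for t in range(120)]
        np.testing.assert_allclose(dhw, expected, atol=1e-9)

    def test_window_forgets_old_hotspots(self):
        temps = [31.0] * 10 + [29.0] * 100  # hotspots leave after 84 days
        dhw = thermal.compute_dhw(daily_log("T2", "2018-01-01", temps), BASE)
        assert dhw["dhw_c_weeks"].iloc[50] == pytest.approx(20 / 7)
        assert dhw["dhw_c_weeks"].iloc[-1] == 0.0

    def test_logger_gap_raises(self):
        log = daily_log("T2", "2018-08-01", [29.0] * 10)
        gap = log[(log["timestamp"] < "2018-08-04")
                  | (log["timestamp"] > "2018-08-06 12:00")]
        with pytest.raises(GapError, match="T2"):
            thermal.compute_dhw(gap, BASE)


class TestGrid:
    def test_grid_spans_min_final_dhw(self, dataset):
        grid = thermal.DhwGrid.from_stress(dataset["stress"], 21)
        finals = (dataset["stress"].sort_values("date")
                  .groupby("tank_id")["dhw_c_weeks"].last())
        assert grid.n_levels == 21
        assert grid.levels[0] == 0.0
        assert grid.levels[-1] == pytest.approx(finals[finals > 0].min())
        np.testing.assert_allclose(np.diff(grid.levels),
                                   np.diff(grid.levels)[0])

    def test_uneven_levels_rejected(self):
        with pytest.raises(ValueError):
            thermal.DhwGrid(np.array([0.0, 1.0, 3.0]))


def _stress_frame(tank, start, dhw_values):
    dates = pd.date_range(start, periods=len(dhw_values))
    return pd.DataFrame({"tank_id": tank, "date": dates,
                         "daily_mean_c": 30.0, "hotspot_c": 1.5,
                         "dhw_c_weeks": dhw_values})


class TestInterpolation:
    def test_step_lookup_between_surveys(self):
        """A fragment first scored bleached at a survey where the tank had
        already passed DHW 5.0 stays healthy at grid level 5.0 and is
        bleached at 5.5."""
        stress = _stress_frame("T2", "2018-08-08",
                               [0.5, 1.5, 2.5, 3.5, 4.5, 4.95, 5.45, 5.95, 6.45])
        records = pd.DataFrame({
            "colony_id": "A01", "fragment_id": "A01-H1", "tank_id": "T2",
            "survey_time": [pd.Timestamp("2018-08-13 10:00"),
                            pd.Timestamp("2018-08-14 10:00")],
            "category": ["healthy", "bleached"]})
        grid = thermal.DhwGrid(np.array([5.0, 5.5]))
        out = thermal.interpolate_health_at_grid(records, stress, grid)
        by_level = out.set_index("dhw_level")["category"]
        assert by_level[5.0] == "healthy"
        assert by_level[5.5] == "bleached"

    def test_always_healthy_fragment(self):
        stress = _stress_frame("T2", "2018-08-08", np.linspace(0, 8, 30))
        records = pd.DataFrame({
            "colony_id": "A01", "fragment_id": "A01-H1", "tank_id": "T2",
            "survey_time": pd.date_range("2018-08-08 10:00", periods=10,
                                         freq="3D"),
            "category": "healthy"})
        grid = thermal.DhwGrid(np.linspace(0, 8, 21))
        out = thermal.interpolate_health_at_grid(records, stress, grid)
        assert len(out) == 21
        assert (out["category"] == "healthy").all()

    def test_tanks_aligned_on_identical_levels(self):
        fast = _stress_frame("T2", "2018-08-08", np.linspace(0, 6, 20))
        slow = _stress_frame("T3", "2018-08-08", np.linspace(0, 6, 20) ** 1.3
                             / 6 ** 0.3)
        stress = pd.concat([fast, slow], ignore_index=True)
        records = pd.DataFrame({
            "colony_id": ["A01"] * 3 + ["A02"] * 3,
            "fragment_id": ["A01-H1"] * 3 + ["A02-H1"] * 3,
            "tank_id": ["T2"] * 3 + ["T3"] * 3,
            "survey_time": list(pd.date_range("2018-08-08 10:00", periods=3,
                                              freq="7D")) * 2,
            "category": ["healthy", "bleached", "dead"] * 2})
        grid = thermal.DhwGrid(np.linspace(0, 6, 13))
        out = thermal.interpolate_health_at_grid(records, stress, grid)
        levels = out.groupby("fragment_id")["dhw_level"].apply(list)
        assert levels["A01-H1"] == levels["A02-H1"]

    def test_tank_short_of_grid_max_raises(self):
        stress = _stress_frame("T2", "2018-08-08", np.linspace(0, 4, 20))
        records = pd.DataFrame({
            "colony_id": ["A01"], "fragment_id": ["A01-H1"],
            "tank_id": ["T2"],
            "survey_time": [pd.Timestamp("2018-08-10 10:00")],
            "category": ["healthy"]})
        grid = thermal.DhwGrid(np.linspace(0, 6, 13))
        with pytest.raises(InsufficientDataError, match="grid maximum"):
            thermal.interpolate_health_at_grid(records, stress, grid)

    def test_interpolated_sequences_non_improving(self, dataset):
        from coraltrade import synth
        stress = dataset["stress"]
        grid = thermal.DhwGrid.from_stress(stress, 21, list(synth.HEAT_TANKS))
        heat = dataset["health"][
            dataset["health"]["tank_id"].isin(synth.HEAT_TANKS)]
        out = thermal.interpolate_health_at_grid(heat, stress, grid)
        w = out["category"].map(CATEGORY_WEIGHT)
        for _, grp in out.assign(w=w).groupby("fragment_id"):
            seq = grp.sort_values("dhw_level")["w"].to_numpy()
            assert (np.diff(seq) >= 0).all()
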