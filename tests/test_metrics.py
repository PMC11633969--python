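"""Daily metric definitions: worked examples, invariances, oracle agreement."""

import math

import numpy as np
import pytest

import _oracles as oracle
from lumipower.metrics import (
    DaySeries,
    MetricConfig,
    compute_day_metrics,
    conditional_window,
    geometric_mean,
    geometric_sd,
    intradaily_variability,
    luminous_exposure,
    mean_timing_relative_to_threshold,
    time_above_threshold,
)


def _day(values, delta_h=1 / 60, valid=None, start_h=0.0):
    values = np.asarray(values, dtype=float)
    n = len(values)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    return DaySeries(
        times_h=start_h + np.arange(n) * delta_h, values=values, valid=valid, delta_h=delta_h
    )


class TestGeometric:
    @pytest.mark.parametrize(
        "values, expected",
        [([10, 1000], 100.0), ([50, 50, 50], 50.0), ([0, 100], 1.0)],
    )
    def test_geometric_mean_examples(self, values, expected):
        assert geometric_mean(np.array(values, float), floor=0.01) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([7, 7, 7], 1.0),
            ([10, 1000], 10.0 ** math.sqrt(2.0)),  # sample SD of {1,3} = sqrt(2)
            ([1, 10, 100], 10.0),                  # sample SD of {0,1,2} = 1
        ],
    )
    def test_geometric_sd_examples(self, values, expected):
        assert geometric_sd(np.array(values, float), floor=0.01) == pytest.approx(
            expected, rel=1e-12
        )

    def test_single_epoch_day_has_no_gsd(self):
        assert math.isnan(geometric_sd(np.array([5.0])))


class TestExposureAndThresholds:
    def test_luminous_exposure_constant_day(self):
        assert luminous_exposure(np.full(1440, 1000.0), 1 / 60) == pytest.approx(24_000.0)

    def test_luminous_exposure_coarse_epochs(self):
        assert luminous_exposure(np.full(30, 100.0), 2 / 60) == pytest.approx(100.0)

    def test_tat_strictly_above(self):
        vals = np.full(1440, 250.0)
        assert time_above_threshold(vals, 1 / 60, 250.0) == 0.0
        assert time_above_threshold(vals + 50, 1 / 60, 250.0) == pytest.approx(24.0)

    def test_tat_half_hour(self):
        vals = np.concatenate([np.full(30, 1500.0), np.full(60, 10.0)])
        assert time_above_threshold(vals, 1 / 60, 1000.0) == pytest.approx(0.5)

    def test_tat_non_increasing_in_threshold(self):
        rng = np.random.default_rng(1)
        vals = 10.0 ** rng.normal(1, 1, 500)
        tats = [time_above_threshold(vals, 1 / 60, thr) for thr in [1, 10, 100, 1000]]
        assert tats == sorted(tats, reverse=True)


class TestMeanTiming:
    def test_mean_of_two_symmetric_epochs_is_noon(self):
        vals = np.array([300.0, 300.0])
        mids = np.array([8.0, 16.0])
        assert mean_timing_relative_to_threshold(vals, mids, 250, "above") == 12.0

    def test_three_qualifying_epochs(self):
        vals = np.array([300.0, 300.0, 300.0, 100.0])
        mids = np.array([6.0, 12.0, 18.0, 3.0])
        assert mean_timing_relative_to_threshold(vals, mids, 250, "above") == 12.0

    def test_no_qualifying_epoch_is_missing(self):
        vals = np.array([100.0, 200.0])
        mids = np.array([9.0, 10.0])
        assert math.isnan(mean_timing_relative_to_threshold(vals, mids, 250, "above"))

    def test_circular_option_agrees_away_from_midnight(self):
        vals = np.array([300.0, 300.0])
        mids = np.array([10.0, 14.0])
        lin = mean_timing_relative_to_threshold(vals, mids, 250, "above")
        circ = mean_timing_relative_to_threshold(vals, mids, 250, "above", circular=True)
        assert circ == pytest.approx(lin, abs=1e-9)


class TestIntradailyVariability:
    def test_constant_day_is_missing(self):
        assert math.isnan(intradaily_variability(_day(np.full(1440, 100.0))))

    def test_linear_ramp_closed_form(self):
        # hourly means ramp over N=24 bins -> IV = 12/(N^2-1) = 12/575
        values = np.repeat(np.arange(24, dtype=float), 60)
        assert intradaily_variability(_day(values)) == pytest.approx(12 / 575, abs=1e-12)

    def test_gap_skips_non_adjacent_pairs(self):
        day = _day(np.repeat([1.0, 5.0, 2.0, 8.0], 60))
        hole = (day.times_h >= 1) & (day.times_h < 2)  # drop hour 1 entirely
        day.valid[hole] = False
        got = intradaily_variability(day)
        want = oracle.iv_oracle(day.times_h, day.values, day.valid)
        assert got == pytest.approx(want, rel=1e-12)


class TestConditionalWindow:
    def test_brightest_window_centers_on_the_plateau(self, square_day):
        mean, mid = conditional_window(square_day, 10.0, "brightest")
        assert mean == pytest.approx(500.0)
        assert mid == pytest.approx(13.0)

    def test_darkest_window_finds_the_night_block(self):
        n = 1440
        times = np.arange(n) / 60.0
        values = np.where(times < 5.0, 0.05, 200.0)
        day = DaySeries(times_h=times, values=values, valid=np.ones(n, bool), delta_h=1 / 60)
        mean, mid = conditional_window(day, 5.0, "darkest")
        assert mean == pytest.approx(0.05)
        assert mid == pytest.approx(2.5)

    def test_constant_day_tie_breaks_to_earliest_window(self):
        day = _day(np.full(1440, 10.0))
        _, mid = conditional_window(day, 5.0, "darkest")
        assert mid == pytest.approx(2.5)

    def test_day_shorter_than_window_is_missing(self):
        day = _day(np.full(120, 10.0))  # 2 h of data
        mean, mid = conditional_window(day, 5.0, "darkest")
        assert math.isnan(mean) and math.isnan(mid)


class TestInvariances:
    def _metrics(self, day, cfg=None):
        cfg = cfg or MetricConfig()
        from lumipower.metrics import _metrics_for_day

        return _metrics_for_day(day, cfg)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        times, values, valid = oracle.random_day(rng)
        day = DaySeries(times, values, valid, 1 / 30)
        c = 3.7
        scaled = DaySeries(times, values * c, valid, 1 / 30)
        cfg = MetricConfig()
        cfg_scaled = MetricConfig(
            mtl_above=250.0 * c, mtl_below=10.0 * c, log_floor=0.01 * c,
        )
        base = self._metrics(day, cfg)
        got = self._metrics(scaled, cfg_scaled)
        for name in ("gm", "le", "m10_mean", "l5_mean"):
            assert got[name] == pytest.approx(c * base[name], rel=1e-9)
        for name in ("gsd", "iv", "m10_mid", "l5_mid", "mtl_above250", "mtl_below10"):
            np.testing.assert_allclose(got[name], base[name], rtol=1e-9)
        # TAT is invariant when the threshold scales along with the values
        assert time_above_threshold(values[valid] * c, 1 / 30, 250.0 * c) == pytest.approx(
            time_above_threshold(values[valid], 1 / 30, 250.0)
        )

    def test_time_shift_equivariance(self):
        n = 1440
        times = np.arange(n) / 60.0
        base_vals = np.where((times >= 8) & (times < 18), 400.0, 0.05)
        shifted_vals = np.where((times >= 9) & (times < 19), 400.0, 0.05)
        day = DaySeries(times, base_vals, np.ones(n, bool), 1 / 60)
        shifted = DaySeries(times, shifted_vals, np.ones(n, bool), 1 / 60)
        m0 = self._metrics(day)
        m1 = self._metrics(shifted)
        for name in ("mtl_above250", "m10_mid"):
            assert m1[name] == pytest.approx(m0[name] + 1.0, abs=1e-6)
        for name in ("gm", "gsd", "le", "iv", "tat250"):
            np.testing.assert_allclose(m1[name], m0[name], rtol=1e-9)


class TestOracleAgreement:
    """Every metric equals its independent brute-force oracle on random days."""

    @pytest.mark.parametrize("seed", range(25))
    def test_all_metrics_match_oracles(self, seed):
        rng = np.random.default_rng(1000 + seed)
        times, values, valid = oracle.random_day(rng, delta_h=1 / 12)
        day = DaySeries(times, values, valid, 1 / 12)
        vals = day.valid_values
        mids = day.valid_mid_times
        cfg = MetricConfig()
        checks = {
            "gm": (geometric_mean(vals, 0.01), oracle.gm_oracle(vals, 0.01)),
            "gsd": (geometric_sd(vals, 0.01), oracle.gsd_oracle(vals, 0.01)),
            "le": (luminous_exposure(vals, day.delta_h), oracle.le_oracle(vals, day.delta_h)),
            "tat250": (
                time_above_threshold(vals, day.delta_h, 250),
                oracle.tat_oracle(vals, day.delta_h, 250),
            ),
            "mtl": (
                mean_timing_relative_to_threshold(vals, mids, 250, "above"),
                oracle.mtl_oracle(vals, mids, 250, "above"),
            ),
            "iv": (
                intradaily_variability(day),
                oracle.iv_oracle(times, values, valid),
            ),
        }
        m10 = conditional_window(day, 10.0, "brightest", cfg.window_min_coverage)
        l5 = conditional_window(day, 5.0, "darkest", cfg.window_min_coverage)
        checks["m10"] = (m10, oracle.window_oracle(times, values, valid, day.delta_h, 10.0, "brightest", cfg.window_min_coverage))
        checks["l5"] = (l5, oracle.window_oracle(times, values, valid, day.delta_h, 5.0, "darkest", cfg.window_min_coverage))
        for name, (got, want) in checks.items():
            np.testing.assert_allclose(got, want, rtol=1e-9, err_msg=name, equal_nan=True)

    def test_l5_mean_no_higher_than_nested_5h_subwindows_of_m10(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            times, values, valid = oracle.random_day(rng, delta_h=1 / 12)
            day = DaySeries(times, values, valid, 1 / 12)
            l5_mean, _ = conditional_window(day, 5.0, "darkest", 0.0)
            if math.isnan(l5_mean):
                continue
            k = int(round(5.0 / day.delta_h))
            n = len(values)
            for start in range(0, n - k + 1, 17):
                sub = values[start : start + k][valid[start : start + k]]
                if len(sub) == 0:
                    continue
                assert l5_mean <= sub.mean() + 1e-9


def test_compute_day_metrics_table_shape(tiny_epoch_table):
    from lumipower.io import regularize
    from lumipower.preprocess import filter_days

    series = regularize(tiny_epoch_table, 120.0)
    series, _ = filter_days(series, 0.8)  # drops the all-missing gap days
    table = compute_day_metrics(series)
    days = series.groupby(["participant_id", "day"]).ngroups
    assert len(table) == days
    for col in MetricConfig().metrics:
        assert col in table.columns
    assert table["gm"].notna().all()


def test_day_without_bright_epochs_has_missing_mtl_only():
    values = np.full(1440, 50.0) + np.linspace(0, 1, 1440)  # varies, never > 250
    table = compute_day_metrics(
        _frame_from_day(values), MetricConfig()
    )
    row = table.iloc[0]
    assert math.isnan(row["mtl_above250"])
    for col in ("gm", "gsd", "le", "tat250", "iv", "m10_mean"):
        assert not math.isnan(row[col])


def _frame_from_day(values):
    import pandas as pd

    n = len(values)
    ts = pd.Timestamp("2015-01-05") + pd.to_timedelta(np.arange(n), "m")
    return pd.DataFrame(
        {
            "participant_id": "p1",
            "timestamp": ts,
            "epoch_s": 60.0,
            "mel_edi": values,
            "valid": True,
            "condition": "winter",
            "day": pd.Timestamp("2015-01-05").date(),
        }
    )
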