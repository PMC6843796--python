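"""Day-counter operators: hand-enumerated cases, oracles, invariants."""

import numpy as np
import pandas as pd
import pytest

from haze_ccdea.met_features import (
    EmptySeriesError,
    build_disaster_panel,
    count_low_wind_days,
    count_no_precip_days,
    count_pm25_pollution_days,
    count_pressure_change_days,
    count_rh_band_days,
    count_temp_change_days,
)
from haze_ccdea.synthetic import WeatherGenConfig, gen_daily_met, gen_pm25


@pytest.mark.parametrize(
    "counter, args, expected",
    [
        # calm-wind threshold is strict: 1.5 itself does not count
        (count_low_wind_days, ([1.0, 2.0, 1.4, 1.5, 0.9],), 3),
        (count_low_wind_days, ([1.5, 1.6, 2.0],), 0),
        (count_no_precip_days, ([0, 0, 1.2, 0, 0],), 4),
        (count_no_precip_days, ([0.1, 5.0, 2.2],), 0),
        # zero change excluded by strict inequality in both change counters
        (count_temp_change_days, ([10, 11, 10.5, 12, 12],), 2),
        (count_pressure_change_days, ([1010, 1008, 1008, 1011],), 1),
        # band inclusive at 60 and 90; the RH=70 day is wet and excluded
        (count_rh_band_days, ([55, 65, 90, 95, 70], [0, 0, 0, 0, 2]), 2),
        (count_rh_band_days, ([50, 50, 50], [0, 0, 0]), 0),
        # "exceeds 75" is strict: 75.0 is not a pollution day
        (count_pm25_pollution_days, ([80, 75, 74.9, 100, 76],), 3),
        (count_pm25_pollution_days, ([10, 75.0, 40],), 0),
    ],
)
def test_hand_enumerated_counts(counter, args, expected):
    assert counter(*args) == expected


def test_monotone_series_change_days():
    n = 40
    assert count_temp_change_days(np.arange(n, dtype=float)) == n - 1
    assert count_pressure_change_days(np.arange(n, 0, -1, dtype=float) + 900) == n - 1


def test_counter_validation_errors():
    with pytest.raises(EmptySeriesError):
        count_low_wind_days([])
    with pytest.raises(ValueError, match="non-negative"):
        count_low_wind_days([1.0, -0.1])
    with pytest.raises(ValueError, match="two days"):
        count_temp_change_days([10.0])
    with pytest.raises(ValueError, match="lo < hi"):
        count_rh_band_days([50.0, 60.0], [0.0, 0.0], lo=90, hi=60)
    with pytest.raises(ValueError):
        count_pm25_pollution_days([-5.0, 80.0])


@pytest.mark.parametrize("seed", range(10))
def test_counters_match_brute_force_filters(seed):
    """Each counter equals an independent one-line predicate filter."""
    met = gen_daily_met(WeatherGenConfig(n_days=365), seed=seed)
    air = gen_pm25(met, seed=seed + 10_000)
    ws = met["wind_speed"].to_numpy()
    pr = met["precipitation"].to_numpy()
    t = met["temperature"].to_numpy()
    p = met["pressure"].to_numpy()
    rh = met["rh"].to_numpy()
    c = air["pm25"].to_numpy()
    assert count_low_wind_days(ws) == sum(1 for v in ws if v < 1.5)
    assert count_no_precip_days(pr) == sum(1 for v in pr if v <= 0)
    assert count_temp_change_days(t) == sum(1 for a, b in zip(t, t[1:]) if b - a > 0)
    assert count_pressure_change_days(p) == sum(1 for a, b in zip(p, p[1:]) if b - a < 0)
    assert count_rh_band_days(rh, pr) == sum(
        1 for h, w in zip(rh, pr) if 60 <= h <= 90 and w == 0
    )
    assert count_pm25_pollution_days(c) == sum(1 for v in c if v > 75)


def test_change_day_partition(met_year):
    """Warming days + non-warming days = N - 1 (first day contributes nothing)."""
    t = met_year["temperature"].to_numpy()
    p = met_year["pressure"].to_numpy()
    n = t.size
    assert count_temp_change_days(t) + np.count_nonzero(np.diff(t) <= 0) == n - 1
    assert count_pressure_change_days(p) + np.count_nonzero(np.diff(p) >= 0) == n - 1


def test_panel_counts_bounded_and_composed(met_year, air_year):
    panel = build_disaster_panel(met_year, air_year)
    assert len(panel) == 1
    row = panel.iloc[0]
    assert row["n_observed_days"] == 365
    for col in ["ws_days", "npd_days", "ptc_days", "npc_days", "rh_days",
                "pm25_pollution_days"]:
        assert 0 <= row[col] <= row["n_observed_days"]
    # composition: panel row equals direct counter calls on the raw arrays
    assert row["ws_days"] == count_low_wind_days(met_year["wind_speed"])
    assert row["pm25_pollution_days"] == count_pm25_pollution_days(air_year["pm25"])


def test_panel_order_independence(met_year, air_year):
    shuffled = met_year.sample(frac=1.0, random_state=0)
    base = build_disaster_panel(met_year, air_year)
    alt = build_disaster_panel(shuffled, air_year)
    pd.testing.assert_frame_equal(base, alt)


def test_leap_year_coverage():
    met = gen_daily_met(WeatherGenConfig(n_days=366), seed=1, start="2016-01-01")
    air = gen_pm25(met, seed=2)
    panel = build_disaster_panel(met, air)
    assert panel.iloc[0]["n_observed_days"] == 366


def test_monthly_panel_sums_to_annual_for_level_counters(met_year, air_year):
    """Level-based counters (thresholds on single days) are additive over
    months; change-day counters lose at most 11 month-boundary days."""
    annual = build_disaster_panel(met_year, air_year, freq="Y").iloc[0]
    monthly = build_disaster_panel(met_year, air_year, freq="M")
    sums = monthly[["ws_days", "npd_days", "rh_days", "pm25_pollution_days"]].sum()
    assert sums["ws_days"] == annual["ws_days"]
    assert sums["npd_days"] == annual["npd_days"]
    assert sums["rh_days"] == annual["rh_days"]
    assert sums["pm25_pollution_days"] == annual["pm25_pollution_days"]
    for col in ["ptc_days", "npc_days"]:
        assert annual[col] - 11 <= monthly[col].sum() <= annual[col]


def test_mismatched_cities_rejected(met_year, air_year):
    other = air_year.assign(city="Elsewhere")
    with pytest.raises(ValueError, match="city sets differ"):
        build_disaster_panel(met_year, other)


def test_aqi_joint_criterion():
    pm = [80.0, 80.0, 76.0]
    cats = ["lightly-polluted", "good", "heavily-polluted"]
    assert count_pm25_pollution_days(pm) == 3
    assert count_pm25_pollution_days(pm, aqi_category=cats) == 2
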