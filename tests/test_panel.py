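"""Indicator-panel assembly: summaries, strategies, deletion, serialisation."""

import numpy as np
import pandas as pd
import pytest

from haze_ccdea.met_features import build_disaster_panel
from haze_ccdea.panel import (
    ACTIVITY_VARIABLES,
    DEFAULT_GROUPS,
    IndicatorPanel,
    build_indicator_panel,
    delete_variables,
    read_panel,
    summarize_variable,
    write_panel,
)
from haze_ccdea.synthetic import (
    WeatherGenConfig,
    gen_activity_table,
    gen_daily_met,
    gen_pm25,
    random_panel,
)


def test_summarize_textbook_case():
    mean, sd = summarize_variable([30.0, 40.0, 50.0])
    assert mean == pytest.approx(40.0)
    assert sd == pytest.approx(10.0)


def test_summarize_single_value_warns():
    with pytest.warns(UserWarning, match="single observation"):
        mean, sd = summarize_variable([7.0])
    assert (mean, sd) == (7.0, 0.0)
    with pytest.raises(ValueError):
        summarize_variable([])


def test_summarize_monte_carlo_recovery():
    rng = np.random.default_rng(42)
    mean, sd = summarize_variable(rng.normal(5.0, 2.0, size=1000))
    assert abs(mean - 5.0) < 0.2
    assert abs(sd - 2.0) < 0.2


@pytest.fixture(scope="module")
def sources():
    cities = [f"City{i}" for i in range(4)]
    years = [2013, 2014, 2015, 2016]
    mets, airs = [], []
    for ci, city in enumerate(cities):
        for yi, year in enumerate(years):
            m = gen_daily_met(
                WeatherGenConfig(n_days=365), seed=100 * ci + yi,
                city=city, start=f"{year}-01-01",
            )
            mets.append(m)
            airs.append(gen_pm25(m, seed=9000 + 100 * ci + yi))
    met = pd.concat(mets, ignore_index=True)
    air = pd.concat(airs, ignore_index=True)
    activity = gen_activity_table(cities, years, seed=7)
    return met, air, activity


def test_monthly_strategy_shapes_and_scaling(sources):
    met, air, activity = sources
    monthly = build_disaster_panel(met, air, freq="M")
    panel = build_indicator_panel(monthly, activity, 2013, sd_strategy="monthly")
    assert panel.input_mean.shape == (4, 14)
    assert panel.output_mean.shape == (4, 1)
    # annualisation: mean of monthly counts x12, sd x sqrt(12)
    city0 = monthly[(monthly["city"] == "City0") & (monthly["year"] == 2013)]
    mu, sd = city0["ws_days"].mean(), city0["ws_days"].std(ddof=1)
    i = panel.input_names.index("WS")
    assert panel.input_mean[0, i] == pytest.approx(12 * mu)
    assert panel.input_sd[0, i] == pytest.approx(np.sqrt(12) * sd)
    # activity SDs default to 5 % of the mean
    j = panel.input_names.index("GOVIE")
    assert panel.input_sd[0, j] == pytest.approx(0.05 * panel.input_mean[0, j])


def test_zero_sd_strategy(sources):
    met, air, activity = sources
    annual = build_disaster_panel(met, air, freq="Y")
    panel = build_indicator_panel(annual, activity, 2014, sd_strategy="zero-sd")
    assert (panel.input_sd == 0).all() and (panel.output_sd == 0).all()


def test_across_years_strategy_recomputes_cellwise(sources):
    met, air, activity = sources
    annual = build_disaster_panel(met, air, freq="Y")
    panel = build_indicator_panel(annual, activity, 2016, sd_strategy="across-years")
    city = panel.dmu_ids[2]
    vals = annual[annual["city"] == city].sort_values("year")["npd_days"].to_numpy()
    i = panel.input_names.index("NPD")
    assert panel.input_mean[2, i] == pytest.approx(vals.mean())
    assert panel.input_sd[2, i] == pytest.approx(vals.std(ddof=1))
    avals = activity[activity["city"] == city].sort_values("year")["TCC"].to_numpy()
    j = panel.input_names.index("TCC")
    assert panel.input_mean[2, j] == pytest.approx(avals.mean())


def test_missing_city_aggregated_error(sources):
    met, air, activity = sources
    annual = build_disaster_panel(met, air, freq="Y")
    with pytest.raises(ValueError, match="only one source"):
        build_indicator_panel(annual, activity[activity["city"] != "City2"], 2013,
                              sd_strategy="zero-sd")


def test_delete_group_and_single():
    panel = random_panel(0, m_inputs=14, groups=True)
    no_mf = delete_variables(panel, "MF")
    assert no_mf.n_inputs == 9
    assert set(no_mf.input_names) == set(ACTIVITY_VARIABLES)
    no_ws = delete_variables(panel, "WS")
    assert no_ws.n_inputs == 13 and "WS" not in no_ws.input_names
    assert no_ws.dmu_ids == panel.dmu_ids
    with pytest.raises(KeyError):
        delete_variables(panel, "NOPE")
    with pytest.raises(ValueError, match="all inputs"):
        delete_variables(panel, list(panel.input_names))


def test_delete_preserves_remaining_columns():
    panel = random_panel(1, m_inputs=14, groups=True)
    reduced = delete_variables(panel, "SP")
    for name in reduced.input_names:
        i_old = panel.input_names.index(name)
        i_new = reduced.input_names.index(name)
        np.testing.assert_array_equal(panel.input_mean[:, i_old],
                                      reduced.input_mean[:, i_new])


def test_scaling_a_variable_scales_its_columns():
    panel = random_panel(3)
    c = 3.7
    k = 4
    scaled = IndicatorPanel(
        panel.dmu_ids, panel.input_names, panel.output_names,
        panel.input_mean * np.where(np.arange(panel.n_inputs) == k, c, 1.0),
        panel.input_sd * np.where(np.arange(panel.n_inputs) == k, c, 1.0),
        panel.output_mean, panel.output_sd,
        input_groups=panel.input_groups,
    )
    np.testing.assert_allclose(scaled.input_mean[:, k], c * panel.input_mean[:, k])
    np.testing.assert_allclose(scaled.input_sd[:, k], c * panel.input_sd[:, k])


def test_panel_invariant_violations_rejected():
    z = np.zeros((2, 1))
    with pytest.raises(ValueError, match="non-negative"):
        IndicatorPanel(("A", "B"), ("x",), ("y",),
                       [[1.0], [1.0]], [[-0.1], [0.0]], [[1.0], [1.0]], z)
    with pytest.raises(ValueError, match="shape"):
        IndicatorPanel(("A", "B"), ("x",), ("y",),
                       [[1.0]], z, [[1.0], [1.0]], z)
    with pytest.raises(ValueError, match="cover"):
        IndicatorPanel(("A", "B"), ("x",), ("y",),
                       [[1.0], [1.0]], z, [[1.0], [1.0]], z,
                       input_groups={"other": "G"})


def test_panel_round_trip(tmp_path):
    panel = random_panel(5, m_inputs=14, groups=True)
    write_panel(panel, tmp_path / "p")
    back = read_panel(tmp_path / "p")
    assert back.dmu_ids == panel.dmu_ids
    assert back.input_names == panel.input_names
    np.testing.assert_allclose(back.input_mean, panel.input_mean)
    np.testing.assert_allclose(back.output_sd, panel.output_sd)
    assert back.input_groups == dict(DEFAULT_GROUPS)
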