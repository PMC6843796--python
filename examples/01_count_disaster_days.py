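"""Count meteorological disaster-point days and PM2.5 pollution days.

Generates one synthetic city-year of daily weather with coupled PM2.5,
then reduces it to the six annual counts that feed the DEA panel.
"""

from haze_ccdea import build_disaster_panel
from haze_ccdea.synthetic import WeatherGenConfig, gen_daily_met, gen_pm25

met = gen_daily_met(WeatherGenConfig(n_days=365), seed=2013, city="DemoCity")
air = gen_pm25(met, seed=2014)

panel = build_disaster_panel(met, air)
row = panel.iloc[0]
print(panel.to_string(index=False))
print()
print(f"Of {row['n_observed_days']} observed days, {row['ws_days']} had calm wind "
      f"(< 1.5 m/s), {row['npd_days']} were precipitation-free, {row['ptc_days']} "
      f"warmed day-over-day, {row['npc_days']} lost pressure, and {row['rh_days']} "
      f"were humid (60-90 % RH) yet dry.")
print(f"{row['pm25_pollution_days']} days exceeded the 75 ug/m3 PM2.5 threshold "
      "(pollution days — the DEA output variable).")
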