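"""Threshold feature extraction from daily weather and air-quality series.

Five meteorological "disaster point" conditions favour PM2.5 accumulation:

* calm wind  — daily mean wind speed strictly below 1.5 m/s,
* dry day    — no measured precipitation,
* warming    — day-over-day temperature change strictly positive,
* pressure drop — day-over-day pressure change strictly negative,
* humid dry day — relative humidity in [60, 90] % on a precipitation-free day.

A PM2.5 pollution day is a day whose 24-h mean concentration strictly
exceeds 75 ug/m3 (the Chinese GB3095-2012 light-pollution threshold).
Annual (or monthly) counts of these six events per city are the raw
material of the DEA panel.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ordered AQI categories; "lightly-polluted" and worse qualify as polluted
AQI_POLLUTED_CATEGORIES = frozenset(
    {"lightly-polluted", "moderately-polluted", "heavily-polluted", "severely-polluted"}
)

MET_COLUMNS = ["date", "city", "wind_speed", "precipitation", "temperature", "pressure", "rh"]
AIR_COLUMNS = ["date", "city", "pm25"]

DISASTER_COUNT_COLUMNS = [
    "ws_days",
    "npd_days",
    "ptc_days",
    "npc_days",
    "rh_days",
    "pm25_pollution_days",
]


class EmptySeriesError(ValueError):
    """Raised when a counter receives an empty daily series."""


def _as_array(values: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(list(values) if not hasattr(values, "__array__") else values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise EmptySeriesError(f"{name} series is empty")
    if np.isnan(arr).any():
        raise ValueError(f"{name} series contains NaN")
    return arr


def count_low_wind_days(wind_speed: Iterable[float], threshold: float = 1.5) -> int:
    """Number of days with mean wind speed strictly below ``threshold`` m/s."""
    ws = _as_array(wind_speed, "wind_speed")
    if (ws < 0).any():
        raise ValueError("wind_speed must be non-negative")
    return int(np.count_nonzero(ws < threshold))


def count_no_precip_days(precipitation: Iterable[float], wet_threshold: float = 0.0) -> int:
    """Number of days with precipitation at or below ``wet_threshold`` mm.

    The default treats exactly 0 mm as "no precipitation"; a small positive
    threshold (e.g. 0.1 mm) models "no effective precipitation" instead.
    """
    pr = _as_array(precipitation, "precipitation")
    if (pr < 0).any():
        raise ValueError("precipitation must be non-negative")
    return int(np.count_nonzero(pr <= wet_threshold))


def count_temp_change_days(temperature: Iterable[float]) -> int:
    """Days whose temperature strictly exceeds the previous day's.

    The first day of the series has no predecessor and contributes nothing;
    a series shorter than two days is rejected.
    """
    t = _as_array(temperature, "temperature")
    if t.size < 2:
        raise ValueError("temperature change needs at least two days")
    return int(np.count_nonzero(np.diff(t) > 0))


def count_pressure_change_days(pressure: Iterable[float]) -> int:
    """Days whose pressure is strictly below the previous day's."""
    p = _as_array(pressure, "pressure")
    if p.size < 2:
        raise ValueError("pressure change needs at least two days")
    if (p <= 0).any():
        raise ValueError("pressure must be positive")
    return int(np.count_nonzero(np.diff(p) < 0))


def count_rh_band_days(
    rh: Iterable[float],
    precipitation: Iterable[float],
    lo: float = 60.0,
    hi: float = 90.0,
    wet_threshold: float = 0.0,
) -> int:
    """Days with relative humidity in ``[lo, hi]`` % (inclusive) and no precipitation."""
    if lo >= hi:
        raise ValueError(f"rh band requires lo < hi, got [{lo}, {hi}]")
    h = _as_array(rh, "rh")
    pr = _as_array(precipitation, "precipitation")
    if h.size != pr.size:
        raise ValueError("rh and precipitation series must have equal length")
    if ((h < 0) | (h > 100)).any():
        raise ValueError("rh must lie in [0, 100]")
    dry = pr <= wet_threshold
    return int(np.count_nonzero((h >= lo) & (h <= hi) & dry))


def count_pm25_pollution_days(
    pm25: Iterable[float],
    threshold: float = 75.0,
    aqi_category: Iterable[str] | None = None,
) -> int:
    """Days whose 24-h mean PM2.5 strictly exceeds ``threshold`` ug/m3.

    When an AQI category series is supplied, a pollution day must in
    addition be classified lightly-polluted or worse; by default the
    criterion is concentration-only (a 24-h mean above 75 ug/m3 already
    implies an individual AQI above the "good" band).
    """
    c = _as_array(pm25, "pm25")
    if (c < 0).any():
        raise ValueError("pm25 concentrations must be non-negative")
    exceed = c > threshold
    if aqi_category is not None:
        cats = np.asarray(list(aqi_category), dtype=object)
        if cats.size != c.size:
            raise ValueError("aqi_category must align with pm25")
        polluted = np.array([str(x) in AQI_POLLUTED_CATEGORIES for x in cats])
        exceed = exceed & polluted
    return int(np.count_nonzero(exceed))


# ---------------------------------------------------------------------------
# record-level validation and panel assembly


def _validate_daily(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing columns {missing}")
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"])
    out = out.sort_values(["city", "date"]).reset_index(drop=True)
    dup = out.duplicated(subset=["city", "date"])
    if dup.any():
        raise ValueError(f"{what} table has duplicate (city, date) rows: {int(dup.sum())}")
    return out


def read_met_csv(path) -> pd.DataFrame:
    """Read a daily meteorological CSV (date, city, wind_speed, precipitation,
    temperature, pressure, rh) and validate it."""
    return _validate_daily(pd.read_csv(path), MET_COLUMNS, "meteorological")


def read_air_csv(path) -> pd.DataFrame:
    """Read a daily PM2.5 CSV (date, city, pm25[, aqi_category]) and validate it."""
    return _validate_daily(pd.read_csv(path), AIR_COLUMNS, "air-quality")


def _counts_for_slice(met: pd.DataFrame, air: pd.DataFrame) -> dict[str, int]:
    # counts are taken over the dates both series observe
    common = met["date"].isin(set(air["date"]))
    met = met[common]
    air = air[air["date"].isin(set(met["date"]))]
    if met.empty:
        raise ValueError("met and air series share no dates in this period")
    row = {
        "ws_days": count_low_wind_days(met["wind_speed"].to_numpy()),
        "npd_days": count_no_precip_days(met["precipitation"].to_numpy()),
        "rh_days": count_rh_band_days(
            met["rh"].to_numpy(), met["precipitation"].to_numpy()
        ),
    }
    temps = met["temperature"].to_numpy()
    pres = met["pressure"].to_numpy()
    row["ptc_days"] = count_temp_change_days(temps) if temps.size >= 2 else 0
    row["npc_days"] = count_pressure_change_days(pres) if pres.size >= 2 else 0
    aqi = air["aqi_category"] if "aqi_category" in air.columns else None
    row["pm25_pollution_days"] = count_pm25_pollution_days(
        air["pm25"].to_numpy(), aqi_category=None if aqi is None else aqi.to_numpy()
    )
    row["n_observed_days"] = int(len(met))
    return row


def build_disaster_panel(
    met: pd.DataFrame,
    air: pd.DataFrame,
    years: Iterable[int] | None = None,
    freq: str = "Y",
) -> pd.DataFrame:
    """Aggregate daily records into disaster-point / pollution-day counts.

    Parameters
    ----------
    met, air
        Validated daily tables (see :func:`read_met_csv` / :func:`read_air_csv`).
    years
        Restrict to these calendar years; default, every year present.
    freq
        ``"Y"`` for one row per (city, year); ``"M"`` for one row per
        (city, year, month).  Change-day counters restart at each period
        boundary, so a period's first day never contributes a change-day.

    Returns a tidy DataFrame with columns city, year[, month], the six
    counters and ``n_observed_days``.  Days missing from the record are
    skipped, not imputed; a warning is logged when a city-year covers less
    than 90 % of the calendar.
    """
    if freq not in {"Y", "M"}:
        raise ValueError("freq must be 'Y' or 'M'")
    met = _validate_daily(met, MET_COLUMNS, "meteorological")
    air = _validate_daily(air, AIR_COLUMNS, "air-quality")
    met_cities, air_cities = set(met["city"]), set(air["city"])
    if met_cities != air_cities:
        raise ValueError(
            f"city sets differ between met ({sorted(met_cities)}) and air ({sorted(air_cities)})"
        )
    rows = []
    for city, mg in met.groupby("city", sort=True):
        ag = air[air["city"] == city]
        year_values = sorted(set(mg["date"].dt.year))
        if years is not None:
            year_values = [y for y in year_values if y in set(years)]
            if not year_values:
                raise ValueError(f"no records for city {city!r} in requested years")
        for year in year_values:
            my = mg[mg["date"].dt.year == year]
            ay = ag[ag["date"].dt.year == year]
            if my.empty or ay.empty:
                raise ValueError(f"city {city!r} year {year} has no paired met/air records")
            n_cal = 366 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 365
            if len(my) < 0.9 * n_cal:
                logger.warning(
                    "city %s year %d covers only %d of %d days", city, year, len(my), n_cal
                )
            if freq == "Y":
                row = {"city": city, "year": year}
                row.update(_counts_for_slice(my, ay))
                rows.append(row)
            else:
                for month in sorted(set(my["date"].dt.month)):
                    mm = my[my["date"].dt.month == month]
                    am = ay[ay["date"].dt.month == month]
                    row = {"city": city, "year": year, "month": month}
                    row.update(_counts_for_slice(mm, am))
                    rows.append(row)
    return pd.DataFrame(rows)
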