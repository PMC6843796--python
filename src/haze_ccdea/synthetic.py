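"""Synthetic inputs for every stage of the pipeline.

Nothing here claims climatological realism beyond the statistical
structure the analysis relies on: temperature and pressure follow AR(1)
processes, wind speed a Weibull law, precipitation a Bernoulli occurrence
with gamma amounts, relative humidity a wet/dry two-regime normal, and
daily PM2.5 a log-normal whose level is pushed up by the number of active
disaster-point conditions that day.  DEA panels can be generated directly
with a planted efficient frontier and a planted influential variable, so
the solver and the deletion scan can be validated against known ground
truth.

All generators are pure functions of (config, seed); per-variable
substreams are split off the seed with ``numpy.random.SeedSequence.spawn``
so each sub-series is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from haze_ccdea.panel import DEFAULT_GROUPS, IndicatorPanel


@dataclass(frozen=True)
class WeatherGenConfig:
    """Parameters of the daily weather generator (one city).

    Defaults are chosen so the five disaster-point counters land in
    plausible annual ranges for a humid subtropical climate (calm-wind
    days ~ 90-130, dry days ~ 220-250, warming / pressure-drop days
    ~ 170-190, humid dry days ~ 100-150); they are documentation values,
    not estimates for any real place.
    """

    n_days: int = 365
    temp_mean: float = 16.0        # deg C
    temp_phi: float = 0.85         # AR(1) persistence, in [0, 1)
    temp_sd: float = 2.5           # innovation SD, deg C
    pressure_mean: float = 1016.0  # hPa
    pressure_phi: float = 0.8
    pressure_sd: float = 3.0
    wind_shape: float = 2.0        # Weibull shape
    wind_scale: float = 2.5        # Weibull scale, m/s
    p_wet: float = 0.35            # precipitation occurrence probability
    rain_shape: float = 0.7        # wet-day gamma shape
    rain_scale: float = 12.0       # wet-day gamma scale, mm
    rh_wet_mean: float = 85.0      # %
    rh_dry_mean: float = 68.0      # %
    rh_sd: float = 12.0

    def validate(self) -> None:
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        for name in ("temp_sd", "pressure_sd", "rh_sd", "wind_shape", "wind_scale",
                     "rain_shape", "rain_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("temp_phi", "pressure_phi"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.p_wet <= 1.0:
            raise ValueError("p_wet must lie in [0, 1]")


def _ar1(rng: np.random.Generator, n: int, mean: float, phi: float, sd: float) -> np.ndarray:
    x = np.empty(n)
    # start from the stationary distribution so the first day is typical
    stat_sd = sd / np.sqrt(1.0 - phi**2) if phi > 0 else sd
    x[0] = mean + rng.normal(0.0, stat_sd)
    eps = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        x[t] = mean + phi * (x[t - 1] - mean) + eps[t - 1]
    return x


def gen_daily_met(
    config: WeatherGenConfig,
    seed: int,
    city: str = "CityA",
    start: str = "2013-01-01",
) -> pd.DataFrame:
    """One city's daily meteorological table (columns as the CSV dialect)."""
    config.validate()
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_t, rng_p, rng_w, rng_r, rng_h = (np.random.default_rng(s) for s in streams)
    n = config.n_days
    temperature = _ar1(rng_t, n, config.temp_mean, config.temp_phi, config.temp_sd)
    pressure = _ar1(rng_p, n, config.pressure_mean, config.pressure_phi, config.pressure_sd)
    wind = config.wind_scale * rng_w.weibull(config.wind_shape, size=n)
    wet = rng_r.random(n) < config.p_wet
    precip = np.where(wet, rng_r.gamma(config.rain_shape, config.rain_scale, size=n), 0.0)
    rh_mean = np.where(wet, config.rh_wet_mean, config.rh_dry_mean)
    rh = np.clip(rng_h.normal(rh_mean, config.rh_sd), 0.0, 100.0)
    return pd.DataFrame(
        {
            "date": pd.date_range(start, periods=n, freq="D"),
            "city": city,
            "wind_speed": wind,
            "precipitation": precip,
            "temperature": temperature,
            "pressure": pressure,
            "rh": rh,
        }
    )


def disaster_indicators(met: pd.DataFrame) -> pd.DataFrame:
    """Daily 0/1 disaster-point indicators for a single-city met table."""
    t = met["temperature"].to_numpy()
    p = met["pressure"].to_numpy()
    dry = met["precipitation"].to_numpy() == 0.0
    rh = met["rh"].to_numpy()
    ind = pd.DataFrame(
        {
            "ws": met["wind_speed"].to_numpy() < 1.5,
            "npd": dry,
            "ptc": np.concatenate([[False], np.diff(t) > 0]),
            "npc": np.concatenate([[False], np.diff(p) < 0]),
            "rh": (rh >= 60.0) & (rh <= 90.0) & dry,
        }
    )
    ind.index = met.index
    return ind


def gen_pm25(
    met: pd.DataFrame,
    seed: int,
    coupling: Sequence[float] = (0.25, 0.25, 0.15, 0.15, 0.2),
    baseline: float = 45.0,
    noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Daily PM2.5 coupled to the five disaster-point indicators.

    log C_d = log(baseline) + sum_k beta_k * I_kd + eps_d,
    eps ~ N(0, noise_sd^2) — so the probability of exceeding the 75 ug/m3
    pollution threshold rises with the number of active disaster
    conditions.  With all couplings zero the exceedance probability is
    exactly ``Phi((log(baseline/75))/noise_sd)``.
    """
    beta = np.asarray(coupling, dtype=float)
    if beta.shape != (5,):
        raise ValueError("coupling must provide 5 coefficients (ws, npd, ptc, npc, rh)")
    if baseline <= 0 or noise_sd < 0:
        raise ValueError("baseline must be > 0 and noise_sd >= 0")
    ind = disaster_indicators(met).to_numpy(dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    log_c = np.log(baseline) + ind @ beta + rng.normal(0.0, noise_sd, size=len(met))
    return pd.DataFrame(
        {"date": met["date"].to_numpy(), "city": met["city"].to_numpy(),
         "pm25": np.exp(log_c)}
    )


#: plausible scales of the nine annual human-activity indicators
_ACTIVITY_RANGES: dict[str, tuple[float, float]] = {
    "GOVIE": (1500.0, 35000.0),   # hundred million yuan
    "UR": (55.0, 82.0),           # %
    "PD": (450.0, 4000.0),        # people per km2
    "BCA": (2000.0, 30000.0),     # 1e4 m2
    "CCO": (50.0, 350.0),         # 1e4 cars
    "NPTVO": (1000.0, 9000.0),    # standard vehicles
    "EC": (0.4, 1.6),             # tce per 1e4 yuan
    "TCC": (800.0, 6000.0),       # 1e4 tce
    "GCRBA": (38.0, 45.0),        # %
}


def gen_activity_table(
    cities: Sequence[str],
    years: Sequence[int],
    seed: int,
    trend: float = 0.03,
) -> pd.DataFrame:
    """Annual human-activity indicators per city with a mild yearly drift."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    base = {}
    for city in cities:
        base[city] = {
            var: rng.uniform(lo, hi) for var, (lo, hi) in _ACTIVITY_RANGES.items()
        }
    for year_idx, year in enumerate(sorted(years)):
        for city in cities:
            row = {"city": city, "year": year}
            for var, (lo, hi) in _ACTIVITY_RANGES.items():
                drift = (1.0 + trend) ** year_idx
                jitter = rng.normal(1.0, 0.02)
                val = base[city][var] * drift * jitter
                row[var] = float(np.clip(val, lo * 0.5, hi * 1.5))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted DEA panels


@dataclass(frozen=True)
class PlantedPanelConfig:
    """Panel generator with known frontier membership and influence structure.

    ``n_efficient`` units are guaranteed BCC-efficient at zero noise: unit 0
    holds uniformly small inputs and the strictly largest output (it
    dominates every non-planted unit), and units ``1..n_efficient-1`` each
    hold the strict minimum of a dedicated input column, which forces
    lambda = e_o in their evaluation.  ``planted_influencer = (dmu, k)``
    additionally plants a unit that holds the strict global minimum of
    input ``k`` and slack-large values of every other input, so its
    efficiency is 1 through the ``k`` constraint alone: deleting ``k``
    (and only ``k``) changes its efficiency.  ``noise_cv`` sets every
    cell's SD to ``noise_cv * mean``.
    """

    n_dmus: int = 8
    m_inputs: int = 5
    s_outputs: int = 1
    n_efficient: int = 3
    noise_cv: float = 0.05
    planted_influencer: tuple[int, int] | None = None

    def validate(self) -> None:
        if not 1 <= self.n_efficient <= self.n_dmus:
            raise ValueError("need 1 <= n_efficient <= n_dmus")
        if self.n_efficient > self.m_inputs:
            raise ValueError(
                "construction needs n_efficient <= m_inputs "
                "(each planted frontier unit owns a dedicated input column)"
            )
        if self.s_outputs != 1:
            raise ValueError("the planted construction supports a single output")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.planted_influencer is not None:
            b, k = self.planted_influencer
            if not 0 <= b < self.n_dmus or not 0 <= k < self.m_inputs:
                raise ValueError("planted_influencer indices out of range")
            if b < self.n_efficient:
                raise ValueError("planted influencer must not be a planted frontier unit")
            if k < self.n_efficient:
                raise ValueError(
                    "planted influencer variable clashes with a dedicated frontier column"
                )


def gen_dea_instance(config: PlantedPanelConfig, seed: int) -> IndicatorPanel:
    """Generate an :class:`IndicatorPanel` with planted structure (see config)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n, m = config.n_dmus, config.m_inputs
    X = rng.uniform(80.0, 150.0, size=(n, m))
    y = rng.uniform(80.0, 110.0, size=n)

    # unit 0: small inputs, strictly largest output -> dominates the rest
    X[0] = rng.uniform(40.0, 60.0, size=m)
    y[0] = 120.0
    # dedicated strict-minimum columns for the other frontier units
    for d in range(1, config.n_efficient):
        X[d, d] = rng.uniform(20.0, 30.0)
    # non-planted units: dominated by unit 0 (inputs above, output below)
    influencer = config.planted_influencer
    for j in range(config.n_efficient, n):
        if influencer is not None and j == influencer[0]:
            continue
        X[j] = X[0] * rng.uniform(1.2, 2.0, size=m)
        y[j] = y[0] * rng.uniform(0.6, 0.95)
    if influencer is not None:
        b, k = influencer
        X[b] = rng.uniform(150.0, 200.0, size=m)  # slack in every other input
        X[b, k] = rng.uniform(10.0, 15.0)         # strict global minimum of input k
        y[b] = rng.uniform(80.0, 100.0)

    cv = config.noise_cv
    return IndicatorPanel(
        dmu_ids=tuple(f"DMU{j:02d}" for j in range(n)),
        input_names=tuple(f"IN{i:02d}" for i in range(m)),
        output_names=("OUT",),
        input_mean=X,
        input_sd=cv * X,
        output_mean=y[:, None],
        output_sd=cv * y[:, None],
        input_groups={f"IN{i:02d}": f"G{i % 3}" for i in range(m)},
        metadata={
            "generator": "planted",
            "seed": seed,
            "n_efficient": config.n_efficient,
            "planted_influencer": influencer,
            "noise_cv": cv,
        },
    )


def random_panel(
    seed: int,
    n_dmus: int = 13,
    m_inputs: int = 14,
    s_outputs: int = 1,
    cv: float = 0.1,
    groups: bool = False,
) -> IndicatorPanel:
    """Unstructured random panel: means U(50,150) in / U(80,120) out, SD = cv*mean.

    With ``groups=True`` and the standard 14-input layout, the study's
    grouping tags are attached so group-level deletion scans can run.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    X = rng.uniform(50.0, 150.0, size=(n_dmus, m_inputs))
    Y = rng.uniform(80.0, 120.0, size=(n_dmus, s_outputs))
    if groups and m_inputs == len(DEFAULT_GROUPS):
        input_names = tuple(DEFAULT_GROUPS)
        input_groups = dict(DEFAULT_GROUPS)
    else:
        input_names = tuple(f"IN{i:02d}" for i in range(m_inputs))
        input_groups = {name: f"G{i % 3}" for i, name in enumerate(input_names)}
    return IndicatorPanel(
        dmu_ids=tuple(f"DMU{j:02d}" for j in range(n_dmus)),
        input_names=input_names,
        output_names=tuple(f"OUT{r}" for r in range(s_outputs)),
        input_mean=X,
        input_sd=cv * X,
        output_mean=Y,
        output_sd=cv * Y,
        input_groups=input_groups,
        metadata={"generator": "random", "seed": seed, "cv": cv},
    )
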