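"""End-to-end orchestration: extract -> panel -> sweep -> scan -> report.

A run consumes the three CSV inputs (daily weather, daily PM2.5, annual
human-activity indicators), builds the per-year DEA panel, sweeps the risk
levels, runs the group- and single-variable deletion scans, and writes
tidy CSV reports plus a manifest capturing every effective setting, so a
re-run with identical inputs and config is byte-identical except for the
manifest timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from haze_ccdea.attribution import (
    JIANGSU_REGIONS,
    check_deletion_monotonicity,
    classify_factors,
    count_changed_cities,
    influence_scan,
    regional_summary,
)
from haze_ccdea.ccdea import DEFAULT_ALPHAS, SolverOptions, efficiency_profile
from haze_ccdea.grey import grey_relational_table
from haze_ccdea.met_features import build_disaster_panel, read_air_csv, read_met_csv
from haze_ccdea.panel import build_indicator_panel, write_panel
from haze_ccdea.synthetic import WeatherGenConfig, gen_activity_table, gen_daily_met, gen_pm25

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    met_path: str
    air_path: str
    activity_path: str
    out_dir: str
    years: list[int] = field(default_factory=list)
    alphas: list[float] = field(default_factory=lambda: list(DEFAULT_ALPHAS))
    sd_strategy: str = "monthly"
    activity_cv: float = 0.05
    change_tol: float = 1e-4
    solver_seed: int = 0
    n_starts: int = 20
    eff_one_tol: float = 1e-4
    region_scheme: str = "south-central-north"
    region_map: dict[str, list[str]] | None = None
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.met_path, self.air_path, self.activity_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if not all(0.0 < a < 1.0 for a in self.alphas):
            raise ValueError("alpha grid must lie strictly within (0, 1)")
        if self.region_map is None and self.region_scheme not in JIANGSU_REGIONS:
            raise ValueError(f"unknown region scheme {self.region_scheme!r}")

    def solver_options(self) -> SolverOptions:
        return SolverOptions(
            n_starts=self.n_starts, seed=self.solver_seed, eff_one_tol=self.eff_one_tol
        )

    def regions(self) -> dict[str, list[str]]:
        return self.region_map or JIANGSU_REGIONS[self.region_scheme]


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]


def sweep_panel(panel, alphas, options) -> pd.DataFrame:
    """Efficiency of every DMU at every risk level (tidy frame)."""
    rows = []
    for o in range(panel.n_dmus):
        for res in efficiency_profile(panel, o, sorted(alphas), options):
            rows.append(
                {
                    "city": panel.dmu_ids[o],
                    "alpha": res.alpha,
                    "theta": res.theta,
                    "efficiency": res.efficiency,
                    "status": res.solver_status,
                    "n_starts_used": res.n_starts_used,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Artifacts: ``disaster_panel.csv``, per-year panel CSVs, per-year
    ``efficiency_profile_<year>.csv`` (efficiency-vs-alpha, one row per
    city and risk level), deletion-scan records and changed-city count
    tables at group and single level, per-city factor classification,
    regional summaries, the grey relational table, and ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    opts = config.solver_options()
    from haze_ccdea import __version__ as pkg_version

    manifest: dict = {
        "package_version": pkg_version,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "stages": {},
    }

    met = read_met_csv(config.met_path)
    air = read_air_csv(config.air_path)
    activity = pd.read_csv(config.activity_path)
    years = config.years or sorted(set(met["date"].dt.year))

    freq = "M" if config.sd_strategy == "monthly" else "Y"
    disaster = build_disaster_panel(met, air, years=years, freq=freq)
    disaster_annual = (
        disaster if freq == "Y"
        else disaster.groupby(["city", "year"], as_index=False).sum().drop(columns="month")
    )
    disaster_annual.to_csv(out / "disaster_panel.csv", index=False)
    manifest["stages"]["extract"] = {
        "n_daily_met": int(len(met)),
        "n_daily_air": int(len(air)),
        "n_panel_rows": int(len(disaster_annual)),
    }

    grey = grey_relational_table(disaster_annual, axis="cities" if len(years) == 1 else "years")
    grey.to_csv(out / "grey_relational.csv", index=False)

    regions = config.regions()
    for year in years:
        panel = build_indicator_panel(
            disaster, activity, year,
            sd_strategy=config.sd_strategy, activity_cv=config.activity_cv,
        )
        write_panel(panel, out / f"panel_{year}")
        profile = sweep_panel(panel, config.alphas, opts)
        profile.to_csv(out / f"efficiency_profile_{year}.csv", index=False)

        baseline = {
            (panel.dmu_index(r.city), r.alpha): r.efficiency
            for r in profile.itertuples()
        }
        scan_records = []
        for mode in ("group", "single"):
            records = influence_scan(
                panel, config.alphas, mode=mode,
                change_tol=config.change_tol, options=opts, baseline=baseline,
            )
            scan_records.extend(records)
            pd.DataFrame([r.__dict__ for r in records]).to_csv(
                out / f"scan_{mode}_{year}.csv", index=False
            )
            count_changed_cities(records, level=mode).to_csv(
                out / f"changed_cities_{mode}_{year}.csv"
            )
        worst = check_deletion_monotonicity(scan_records)
        if worst > 1e-6:
            logger.warning("year %d: deletion increased an efficiency by %.2e", year, worst)

        factors = classify_factors(scan_records)
        (out / f"factors_{year}.json").write_text(
            json.dumps({c: {str(a): v for a, v in d.items()} for c, d in factors.items()},
                       indent=2, sort_keys=True)
        )
        try:
            regional = regional_summary(
                [r for r in scan_records if r.level == "group"], regions
            )
            regional.to_csv(out / f"regional_summary_{year}.csv", index=False)
        except ValueError as exc:
            logger.warning("regional summary skipped for %d: %s", year, exc)
            manifest["stages"].setdefault("warnings", []).append(str(exc))

        if config.make_plots:
            _plot_profiles(profile, out / f"efficiency_profile_{year}.png", year)

        manifest["stages"][f"year_{year}"] = {
            "n_dmus": panel.n_dmus,
            "n_inputs": panel.n_inputs,
            "n_scan_records": len(scan_records),
            "max_deletion_delta": float(worst),
            "solver_status_counts": profile["status"].value_counts().to_dict(),
        }

    manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _plot_profiles(profile: pd.DataFrame, path: Path, year: int) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for city, sub in profile.groupby("city"):
        ax.plot(sub["alpha"], sub["efficiency"], marker="o", ms=3, label=city)
    ax.set_xlabel("risk level alpha")
    ax.set_ylabel("stochastic efficiency (1/theta)")
    ax.set_title(f"Efficiency profiles, {year}")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def generate_synthetic_bundle(
    out_dir: str | Path,
    seed: int,
    cities: Sequence[str] | None = None,
    years: Sequence[int] = (2013,),
    weather: WeatherGenConfig | None = None,
) -> dict[str, Path]:
    """Write a coherent synthetic (met, air, activity) CSV bundle.

    Emulates the pipeline's real inputs: one daily weather and PM2.5
    series per city per year (PM2.5 coupled to the disaster conditions),
    plus the annual activity table.  Returns the three file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cities = list(cities) if cities is not None else [f"City{c}" for c in "ABCDEFGH"]
    years = sorted(years)
    ss = np.random.SeedSequence(seed)
    met_frames, air_frames = [], []
    for ci, city in enumerate(cities):
        for yi, year in enumerate(years):
            n_days = 366 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 365
            cfg = weather or WeatherGenConfig()
            cfg = WeatherGenConfig(**{**cfg.__dict__, "n_days": n_days})
            sub_seed = int(ss.generate_state(1)[0] % (2**31)) + ci * 1000 + yi
            m = gen_daily_met(cfg, seed=sub_seed, city=city, start=f"{year}-01-01")
            a = gen_pm25(m, seed=sub_seed + 500_000)
            met_frames.append(m)
            air_frames.append(a)
    met = pd.concat(met_frames, ignore_index=True)
    air = pd.concat(air_frames, ignore_index=True)
    activity = gen_activity_table(cities, years, seed=int(ss.generate_state(2)[1] % (2**31)))
    paths = {
        "met": out / "met_daily.csv",
        "air": out / "air_daily.csv",
        "activity": out / "activity_annual.csv",
    }
    met.to_csv(paths["met"], index=False)
    air.to_csv(paths["air"], index=False)
    activity.to_csv(paths["activity"], index=False)
    return paths
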