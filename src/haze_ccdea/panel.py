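"""Assembly of the DEA data block: per-city means and SDs of 14 inputs, 1 output.

The evaluated units (DMUs) are cities.  Inputs are the five annual
disaster-point day counts plus nine human-activity indicators grouped as
industrial development (ID), social progress (SP), transportation (T),
energy utilization (EU) and ecological protection (EP); the single output
is the annual number of PM2.5 pollution days.  The stochastic DEA model
needs a mean and a standard deviation for every cell; annual yearbook data
carry no within-year replication, so the SD is estimated by a selectable
strategy (see :func:`build_indicator_panel`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Table-2 style variable system: met counters + human-activity indicators.
MET_VARIABLES = ["WS", "NPD", "PTC", "NPC", "RH"]
ACTIVITY_VARIABLES = ["GOVIE", "UR", "PD", "BCA", "CCO", "NPTVO", "EC", "TCC", "GCRBA"]
OUTPUT_VARIABLE = "PM25_DAYS"

#: grouping tags of the 14 inputs: meteorological factors (MF), industrial
#: development (ID), social progress (SP), transportation (T), energy
#: utilization (EU), ecological protection (EP)
DEFAULT_GROUPS: dict[str, str] = {
    "WS": "MF",
    "NPD": "MF",
    "PTC": "MF",
    "NPC": "MF",
    "RH": "MF",
    "GOVIE": "ID",
    "UR": "SP",
    "PD": "SP",
    "BCA": "SP",
    "CCO": "T",
    "NPTVO": "T",
    "EC": "EU",
    "TCC": "EU",
    "GCRBA": "EP",
}

_MET_TO_COUNT = {
    "WS": "ws_days",
    "NPD": "npd_days",
    "PTC": "ptc_days",
    "NPC": "npc_days",
    "RH": "rh_days",
}

SD_STRATEGIES = ("monthly", "across-years", "zero-sd")


@dataclass(frozen=True)
class IndicatorPanel:
    """Means and standard deviations of inputs/outputs for n DMUs.

    Shapes: ``input_mean``/``input_sd`` are (n, m); ``output_mean``/
    ``output_sd`` are (n, s).  ``input_groups`` maps every input name to
    its grouping tag.
    """

    dmu_ids: tuple[str, ...]
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    input_mean: np.ndarray
    input_sd: np.ndarray
    output_mean: np.ndarray
    output_sd: np.ndarray
    input_groups: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n, m, s = len(self.dmu_ids), len(self.input_names), len(self.output_names)
        object.__setattr__(self, "dmu_ids", tuple(self.dmu_ids))
        object.__setattr__(self, "input_names", tuple(self.input_names))
        object.__setattr__(self, "output_names", tuple(self.output_names))
        for name, arr, shape in (
            ("input_mean", self.input_mean, (n, m)),
            ("input_sd", self.input_sd, (n, m)),
            ("output_mean", self.output_mean, (n, s)),
            ("output_sd", self.output_sd, (n, s)),
        ):
            a = np.asarray(arr, dtype=float)
            if a.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {a.shape}")
            if not np.isfinite(a).all():
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, a)
        if (self.input_sd < 0).any() or (self.output_sd < 0).any():
            raise ValueError("standard deviations must be non-negative")
        if m == 0:
            raise ValueError("panel needs at least one input")
        if s == 0:
            raise ValueError("panel needs at least one output")
        if self.input_groups:
            unknown = set(self.input_groups) - set(self.input_names)
            uncovered = set(self.input_names) - set(self.input_groups)
            if unknown or uncovered:
                raise ValueError(
                    f"input_groups must cover inputs exactly once "
                    f"(unknown={sorted(unknown)}, uncovered={sorted(uncovered)})"
                )

    @property
    def n_dmus(self) -> int:
        return len(self.dmu_ids)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    @property
    def n_outputs(self) -> int:
        return len(self.output_names)

    def groups(self) -> dict[str, list[str]]:
        """Group tag -> member input names, in panel column order."""
        out: dict[str, list[str]] = {}
        for name in self.input_names:
            tag = self.input_groups.get(name, name)
            out.setdefault(tag, []).append(name)
        return out

    def dmu_index(self, dmu_id: str) -> int:
        try:
            return self.dmu_ids.index(dmu_id)
        except ValueError:
            raise KeyError(f"unknown DMU {dmu_id!r}") from None


def summarize_variable(values: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Sample mean and sample SD (n-1 denominator) of a variable's values.

    A single observation yields SD 0 with a warning — the stochastic model
    then treats the cell as deterministic.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("summarize_variable needs a non-empty 1-D sequence")
    if not np.isfinite(arr).all():
        raise ValueError("values contain non-finite entries")
    if arr.size == 1:
        warnings.warn("single observation: SD set to 0", stacklevel=2)
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing columns {missing}")


def build_indicator_panel(
    disaster: pd.DataFrame,
    activity: pd.DataFrame,
    year: int,
    sd_strategy: str = "monthly",
    activity_cv: float = 0.05,
    window: int = 4,
) -> IndicatorPanel:
    """Build the (n x 14 inputs, n x 1 output) DEA panel for one year.

    Parameters
    ----------
    disaster
        Disaster panel from :func:`haze_ccdea.met_features.build_disaster_panel`;
        monthly rows (``freq="M"``) for the ``"monthly"`` strategy, annual
        rows otherwise.
    activity
        Annual human-activity table with columns city, year and the nine
        indicator columns (GOVIE, UR, PD, BCA, CCO, NPTVO, EC, TCC, GCRBA).
    sd_strategy
        ``"monthly"``   — day counters: mean and SD of the 12 monthly
        sub-counts, annualised as mean*12 and SD*sqrt(12) (months treated
        as independent); activity indicators are annual scalars, so their
        SD defaults to ``activity_cv`` times the mean.
        ``"across-years"`` — mean/SD of each city-variable cell over the
        ``window`` years ending at ``year`` (both sources must cover them).
        ``"zero-sd"``   — the given year's values with all SDs zero
        (deterministic DEA mode).
    """
    if sd_strategy not in SD_STRATEGIES:
        raise ValueError(f"sd_strategy must be one of {SD_STRATEGIES}")
    _require_columns(activity, ["city", "year"] + ACTIVITY_VARIABLES, "activity")
    _require_columns(
        disaster, ["city", "year"] + list(_MET_TO_COUNT.values()) + ["pm25_pollution_days"],
        "disaster",
    )
    if sd_strategy == "monthly" and "month" not in disaster.columns:
        raise ValueError("'monthly' strategy needs a monthly disaster panel (freq='M')")

    cities = sorted(set(disaster["city"]) & set(activity["city"]))
    problems = []
    for c in sorted(set(disaster["city"]) ^ set(activity["city"])):
        problems.append(f"city {c!r} present in only one source")
    if not cities:
        problems.append("no city present in both sources")
    if problems:
        raise ValueError("; ".join(problems))

    if sd_strategy == "across-years":
        years = list(range(year - window + 1, year + 1))
    else:
        years = [year]

    input_names = MET_VARIABLES + ACTIVITY_VARIABLES
    n, m = len(cities), len(input_names)
    in_mean = np.zeros((n, m))
    in_sd = np.zeros((n, m))
    out_mean = np.zeros((n, 1))
    out_sd = np.zeros((n, 1))
    errors: list[str] = []

    for ci, city in enumerate(cities):
        drows = disaster[(disaster["city"] == city) & disaster["year"].isin(years)]
        arows = activity[(activity["city"] == city) & activity["year"].isin(years)]
        if drows.empty:
            errors.append(f"{city}: no disaster rows for {years}")
            continue
        if arows.empty:
            errors.append(f"{city}: no activity rows for {years}")
            continue

        if sd_strategy == "monthly":
            for k, var in enumerate(MET_VARIABLES):
                mu, sd = summarize_variable(drows[_MET_TO_COUNT[var]].to_numpy())
                in_mean[ci, k], in_sd[ci, k] = mu * 12.0, sd * np.sqrt(12.0)
            mu, sd = summarize_variable(drows["pm25_pollution_days"].to_numpy())
            out_mean[ci, 0], out_sd[ci, 0] = mu * 12.0, sd * np.sqrt(12.0)
            arow = arows[arows["year"] == year]
            if arow.empty:
                errors.append(f"{city}: no activity row for {year}")
                continue
            for k, var in enumerate(ACTIVITY_VARIABLES, start=len(MET_VARIABLES)):
                v = float(arow.iloc[0][var])
                in_mean[ci, k], in_sd[ci, k] = v, activity_cv * abs(v)
        elif sd_strategy == "across-years":
            if set(drows["year"]) != set(years) or set(arows["year"]) != set(years):
                errors.append(f"{city}: window {years} not fully covered")
                continue
            drows = drows.sort_values("year")
            arows = arows.sort_values("year")
            for k, var in enumerate(MET_VARIABLES):
                in_mean[ci, k], in_sd[ci, k] = summarize_variable(
                    drows[_MET_TO_COUNT[var]].to_numpy()
                )
            for k, var in enumerate(ACTIVITY_VARIABLES, start=len(MET_VARIABLES)):
                in_mean[ci, k], in_sd[ci, k] = summarize_variable(arows[var].to_numpy())
            out_mean[ci, 0], out_sd[ci, 0] = summarize_variable(
                drows["pm25_pollution_days"].to_numpy()
            )
        else:  # zero-sd
            drow = drows[drows["year"] == year]
            arow = arows[arows["year"] == year]
            if drow.empty or arow.empty:
                errors.append(f"{city}: missing {year} row")
                continue
            if "month" in disaster.columns and drow["month"].notna().any():
                agg = drow[list(_MET_TO_COUNT.values()) + ["pm25_pollution_days"]].sum()
            else:
                agg = drow.iloc[0]
            for k, var in enumerate(MET_VARIABLES):
                in_mean[ci, k] = float(agg[_MET_TO_COUNT[var]])
            for k, var in enumerate(ACTIVITY_VARIABLES, start=len(MET_VARIABLES)):
                in_mean[ci, k] = float(arow.iloc[0][var])
            out_mean[ci, 0] = float(agg["pm25_pollution_days"])

    if errors:
        raise ValueError("panel construction failed: " + "; ".join(errors))

    return IndicatorPanel(
        dmu_ids=tuple(cities),
        input_names=tuple(input_names),
        output_names=(OUTPUT_VARIABLE,),
        input_mean=in_mean,
        input_sd=in_sd,
        output_mean=out_mean,
        output_sd=out_sd,
        input_groups=dict(DEFAULT_GROUPS),
        metadata={"year": year, "sd_strategy": sd_strategy, "activity_cv": activity_cv},
    )


def delete_variables(panel: IndicatorPanel, target: str | Sequence[str]) -> IndicatorPanel:
    """Return a panel without the named input column(s) or grouping tag.

    ``target`` may be a single input name, a group tag (resolved through
    ``panel.input_groups``), or a sequence of names.  The DMU set and the
    outputs are untouched; deleting every input is refused.
    """
    groups = panel.groups()
    if isinstance(target, str):
        if target in groups and target not in panel.input_names:
            names = list(groups[target])
        elif target in panel.input_names:
            names = [target]
        else:
            raise KeyError(f"unknown input or group {target!r}")
    else:
        names = list(target)
        unknown = [t for t in names if t not in panel.input_names]
        if unknown:
            raise KeyError(f"unknown inputs {unknown}")
    keep = [i for i, name in enumerate(panel.input_names) if name not in set(names)]
    if not keep:
        raise ValueError("cannot delete all inputs")
    kept_names = tuple(panel.input_names[i] for i in keep)
    return replace(
        panel,
        input_names=kept_names,
        input_mean=panel.input_mean[:, keep],
        input_sd=panel.input_sd[:, keep],
        input_groups={k: v for k, v in panel.input_groups.items() if k in kept_names},
        metadata={**panel.metadata, "deleted": tuple(names)},
    )


# ---------------------------------------------------------------------------
# serialisation: two CSVs (means, sds) + JSON metadata sidecar


def write_panel(panel: IndicatorPanel, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cols = list(panel.input_names) + list(panel.output_names)
    means = pd.DataFrame(
        np.hstack([panel.input_mean, panel.output_mean]), index=list(panel.dmu_ids), columns=cols
    )
    sds = pd.DataFrame(
        np.hstack([panel.input_sd, panel.output_sd]), index=list(panel.dmu_ids), columns=cols
    )
    means.to_csv(f"{prefix}_means.csv", index_label="city")
    sds.to_csv(f"{prefix}_sds.csv", index_label="city")
    meta = {
        "input_names": list(panel.input_names),
        "output_names": list(panel.output_names),
        "input_groups": panel.input_groups,
        "metadata": {k: v for k, v in panel.metadata.items() if _json_ok(v)},
    }
    Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


def read_panel(prefix: str | Path) -> IndicatorPanel:
    means = pd.read_csv(f"{prefix}_means.csv", index_col="city")
    sds = pd.read_csv(f"{prefix}_sds.csv", index_col="city")
    meta = json.loads(Path(f"{prefix}_meta.json").read_text())
    inp, outp = meta["input_names"], meta["output_names"]
    return IndicatorPanel(
        dmu_ids=tuple(str(c) for c in means.index),
        input_names=tuple(inp),
        output_names=tuple(outp),
        input_mean=means[inp].to_numpy(),
        input_sd=sds[inp].to_numpy(),
        output_mean=means[outp].to_numpy(),
        output_sd=sds[outp].to_numpy(),
        input_groups=meta.get("input_groups", {}),
        metadata=meta.get("metadata", {}),
    )


def _json_ok(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
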