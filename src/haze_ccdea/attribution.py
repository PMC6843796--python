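"""Variable-deletion influence analysis and regional aggregation.

A factor (single input variable or grouping of variables) is said to
influence a city's PM2.5 pollution days if deleting it from the input
system changes the city's stochastic efficiency at some risk level.
Deleting an input removes its constraint, which can only enlarge the
feasible set of the program — so theta can only grow and the efficiency
can only drop; "changed" therefore means "dropped by more than
``change_tol``".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from haze_ccdea.ccdea import DEFAULT_ALPHAS, SolverOptions, efficiency_profile
from haze_ccdea.panel import IndicatorPanel, delete_variables

logger = logging.getLogger(__name__)

#: the 13 prefecture-level cities grouped as in the study region
JIANGSU_REGIONS: dict[str, dict[str, list[str]]] = {
    "south-central-north": {
        "Southern": ["Nanjing", "Zhenjiang", "Suzhou", "Wuxi", "Changzhou"],
        "Central": ["Yangzhou", "Taizhou", "Nantong"],
        "Northern": ["Xuzhou", "Lianyungang", "Huaian", "Yancheng", "Suqian"],
    },
    "coastal-inland": {
        "Coastal": ["Nantong", "Lianyungang", "Yancheng"],
        "Inland": [
            "Nanjing", "Xuzhou", "Changzhou", "Suzhou", "Yangzhou",
            "Taizhou", "Wuxi", "Zhenjiang", "Huaian", "Suqian",
        ],
    },
}


@dataclass(frozen=True)
class InfluenceRecord:
    city_id: str
    deleted: str
    level: str  # "group" or "single"
    alpha: float
    eff_baseline: float
    eff_deleted: float
    changed: bool
    delta: float
    status: str = "ok"


def _records_frame(records: Iterable[InfluenceRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def influence_scan(
    panel: IndicatorPanel,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    mode: str = "single",
    change_tol: float = 1e-4,
    options: SolverOptions | None = None,
    baseline: Mapping[tuple[int, float], float] | None = None,
) -> list[InfluenceRecord]:
    """Re-solve every DMU after deleting each variable (or group) in turn.

    Returns one record per (deletion target, DMU, alpha).  ``mode`` selects
    single input variables or grouping tags as deletion targets; the output
    variable is never deletable.  Solver failures are flagged on the record
    (status ``"error"``) rather than aborting the scan.

    ``baseline`` may carry pre-computed baseline efficiencies keyed by
    (dmu index, alpha); otherwise the baseline profile is solved here.
    """
    if mode not in {"single", "group"}:
        raise ValueError("mode must be 'single' or 'group'")
    if panel.n_inputs < 2:
        raise ValueError("influence scan needs at least two inputs")
    opts = options or SolverOptions()
    alphas = sorted(alphas)

    if baseline is None:
        baseline = {}
        for o in range(panel.n_dmus):
            for res in efficiency_profile(panel, o, alphas, opts):
                baseline[(o, res.alpha)] = res.efficiency

    targets = list(panel.groups()) if mode == "group" else list(panel.input_names)
    records: list[InfluenceRecord] = []
    for target in targets:
        try:
            reduced = delete_variables(panel, target)
        except ValueError as exc:  # deleting the only remaining input
            logger.warning("skipping deletion of %s: %s", target, exc)
            continue
        for o in range(panel.n_dmus):
            profile = efficiency_profile(reduced, o, alphas, opts)
            for res in profile:
                base = baseline[(o, res.alpha)]
                eff = res.efficiency
                status = res.solver_status
                if status == "error" or not np.isfinite(eff):
                    records.append(
                        InfluenceRecord(
                            panel.dmu_ids[o], target, mode, res.alpha,
                            base, float("nan"), False, float("nan"), status="error",
                        )
                    )
                    continue
                delta = eff - base
                records.append(
                    InfluenceRecord(
                        panel.dmu_ids[o], target, mode, res.alpha,
                        base, eff, bool(abs(delta) > change_tol), delta,
                    )
                )
    return records


def count_changed_cities(
    records: Iterable[InfluenceRecord], level: str | None = None
) -> pd.DataFrame:
    """Count of cities flagged as changed, per deleted target and risk level.

    Rows are deletion targets, columns risk levels; an empty record set
    yields an empty all-zero table.
    """
    recs = [r for r in records if level is None or r.level == level]
    if not recs:
        return pd.DataFrame()
    df = _records_frame(recs)
    table = (
        df[df["changed"]]
        .groupby(["deleted", "alpha"])["city_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    # keep every scanned target and alpha, even if nothing changed
    all_targets = sorted(df["deleted"].unique())
    all_alphas = sorted(df["alpha"].unique())
    return table.reindex(index=all_targets, columns=all_alphas, fill_value=0).astype(int)


def classify_factors(records: Iterable[InfluenceRecord]) -> dict[str, dict[float, list[str]]]:
    """Per-city influencing factors, partitioned by the risk levels at which
    they were flagged: ``{city: {alpha: [deleted names...]}}``."""
    out: dict[str, dict[float, list[str]]] = {}
    for r in records:
        if r.changed:
            out.setdefault(r.city_id, {}).setdefault(r.alpha, []).append(r.deleted)
    for city in out:
        for alpha in out[city]:
            out[city][alpha] = sorted(set(out[city][alpha]))
    return out


def regional_summary(
    records: Iterable[InfluenceRecord],
    region_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Flag counts and ranking of deletion targets per region.

    ``region_map`` maps region name -> list of city ids and must cover
    every city appearing in the records.  Returns a tidy frame with
    columns (region, deleted, n_flags, rank), ranked within region by
    descending flag count over all (city, alpha) pairs.
    """
    recs = list(records)
    df = _records_frame(recs)
    if df.empty:
        return pd.DataFrame(columns=["region", "deleted", "n_flags", "rank"])
    city_to_region = {}
    for region, cities in region_map.items():
        for c in cities:
            city_to_region[c] = region
    missing = sorted(set(df["city_id"]) - set(city_to_region))
    if missing:
        raise ValueError(f"cities missing from region map: {missing}")
    df["region"] = df["city_id"].map(city_to_region)
    targets = sorted(df["deleted"].unique())
    rows = []
    for region in region_map:
        sub = df[(df["region"] == region) & df["changed"]]
        counts = sub.groupby("deleted").size()
        for t in targets:
            rows.append({"region": region, "deleted": t, "n_flags": int(counts.get(t, 0))})
    out = pd.DataFrame(rows)
    out["rank"] = (
        out.groupby("region")["n_flags"].rank(method="min", ascending=False).astype(int)
    )
    return out.sort_values(["region", "rank", "deleted"]).reset_index(drop=True)


def check_deletion_monotonicity(
    records: Iterable[InfluenceRecord], tol: float = 1e-6
) -> float:
    """Largest positive efficiency increase across records (should be <= tol).

    Deleting an input relaxes the program, so the efficiency after deletion
    can never exceed the baseline beyond numerical tolerance.  Returns the
    maximum observed ``eff_deleted - eff_baseline`` (0 for an empty or
    all-error record set) so callers can assert it.
    """
    worst = 0.0
    for r in records:
        if r.status == "ok" and np.isfinite(r.delta):
            worst = max(worst, r.delta)
    return worst
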