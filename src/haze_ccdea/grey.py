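"""Grey relational analysis between disaster-point and pollution-day series.

Deng's formulation: after normalising the reference and comparison series,
the pointwise coefficient is

    xi(k) = (d_min + rho * d_max) / (d(k) + rho * d_max),

with d(k) = |ref(k) - cmp(k)| and d_min/d_max the global extrema of d over
the pair; the relational grade is the mean of xi(k).  The distinguishing
coefficient rho in (0, 1] damps the dominance of d_max (0.5 by custom).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NORMALIZATIONS = ("initial", "mean", "none")


def _normalize(arr: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return arr
    ref = arr[0] if how == "initial" else arr.mean()
    if ref == 0:
        raise ValueError(f"cannot {how}-normalize a series whose {how} value is 0")
    return arr / ref


def grey_relational_grade(
    reference: Sequence[float],
    comparison: Sequence[float],
    rho: float = 0.5,
    normalization: str = "initial",
) -> float:
    """Deng grey relational grade of ``comparison`` against ``reference``.

    Returns a value in (0, 1]; 1 exactly when the normalised series
    coincide.  Symmetric in its two series (shared extrema, absolute
    differences).
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho must lie in (0, 1], got {rho}")
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    ref = np.asarray(reference, dtype=float)
    cmp_ = np.asarray(comparison, dtype=float)
    if ref.ndim != 1 or ref.size < 2:
        raise ValueError("series must be 1-D with length >= 2")
    if ref.shape != cmp_.shape:
        raise ValueError(f"length mismatch: {ref.size} vs {cmp_.size}")
    if not (np.isfinite(ref).all() and np.isfinite(cmp_).all()):
        raise ValueError("series contain non-finite values")
    ref = _normalize(ref, normalization)
    cmp_ = _normalize(cmp_, normalization)
    d = np.abs(ref - cmp_)
    d_min, d_max = d.min(), d.max()
    if d_max == 0.0:  # identical after normalisation
        return 1.0
    xi = (d_min + rho * d_max) / (d + rho * d_max)
    return float(xi.mean())


def grey_relational_table(
    disaster_panel: pd.DataFrame,
    variables: Iterable[str] = ("ws_days", "npd_days", "ptc_days", "npc_days", "rh_days"),
    reference: str = "pm25_pollution_days",
    axis: str = "years",
    rho: float = 0.5,
    normalization: str = "initial",
) -> pd.DataFrame:
    """Grades of each disaster-point series against the pollution-day series.

    ``axis="years"`` compares the multi-year series within each city (one
    row per city); ``axis="cities"`` compares the cross-city series within
    each year (one row per year).  Both views are supported because the
    screening can be read either way.
    """
    if axis not in {"years", "cities"}:
        raise ValueError("axis must be 'years' or 'cities'")
    group_col, order_col = ("city", "year") if axis == "years" else ("year", "city")
    rows = []
    for key, sub in disaster_panel.groupby(group_col):
        sub = sub.sort_values(order_col)
        ref = sub[reference].to_numpy(dtype=float)
        row = {group_col: key}
        for var in variables:
            row[var] = grey_relational_grade(
                ref, sub[var].to_numpy(dtype=float), rho=rho, normalization=normalization
            )
        rows.append(row)
    return pd.DataFrame(rows)
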