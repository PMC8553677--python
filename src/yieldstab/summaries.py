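"""Per-class summaries, the two-algorithm contingency table, and tidy exports.

These summaries characterize the stability classes once a map exists:
per-class mean yield and within-class spread per year, per-pixel temporal
variability averaged by class, the cross-tabulation of the two algorithms'
maps, and the per-field covariate table consumed by downstream mixed-model
tools (the models themselves are out of scope here; the tables are tidy
DataFrames ready for any standard package).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster_core import (
    CLASS_HIGH_STABLE,
    CLASS_LOW_STABLE,
    CLASS_NAMES,
    CLASS_UNSTABLE,
    StabilityMap,
    YieldMap,
    YieldStack,
)
from .uncertainty import class_fractions

__all__ = [
    "class_mean_yield",
    "within_class_sd",
    "temporal_variability",
    "algorithm_contingency",
    "mean_contingency",
    "covariate_table",
]

_THREE_CLASSES = (CLASS_LOW_STABLE, CLASS_HIGH_STABLE, CLASS_UNSTABLE)


def _check_aligned(smap: StabilityMap, ymap: YieldMap) -> None:
    if smap.shape != ymap.shape:
        raise ValueError("stability map and yield map grids differ")


def class_mean_yield(
    stability: StabilityMap, raw_maps: Sequence[YieldMap]
) -> pd.DataFrame:
    """Mean raw yield per (crop, year, stability class).

    One row per class present in each year's map; pixels must be valid in
    both the stability map and that year's raw map.
    """
    rows = []
    for ymap in raw_maps:
        _check_aligned(stability, ymap)
        both = stability.valid_mask & ymap.valid_mask
        for c in _THREE_CLASSES:
            sel = both & (stability.classes == c)
            n = int(sel.sum())
            if n == 0:
                continue
            rows.append(
                {
                    "crop": ymap.crop.value,
                    "year": ymap.year,
                    "stability_class": CLASS_NAMES[c],
                    "mean_yield": float(ymap.values[sel].mean()),
                    "n_pixels": n,
                }
            )
    return pd.DataFrame(rows)


def within_class_sd(stability: StabilityMap, ymap: YieldMap) -> dict[str, float]:
    """Sample SD of same-class pixel values within one map.

    Classes with fewer than 2 pixels are omitted (SD undefined).
    """
    _check_aligned(stability, ymap)
    both = stability.valid_mask & ymap.valid_mask
    out = {}
    for c in _THREE_CLASSES:
        sel = both & (stability.classes == c)
        if int(sel.sum()) >= 2:
            out[CLASS_NAMES[c]] = float(ymap.values[sel].std(ddof=1))
    return out


def temporal_variability(
    stack: YieldStack,
    stability: StabilityMap,
    field_id: str | None = None,
    state: str = "",
    farmer_id: str = "",
) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-pixel temporal SD across a crop's years, summarized by class.

    Returns (per-class mean temporal SD, long-form table with one row per
    pixel: temporal_sd, field, stability class, crop, state, farmer) — the
    shape expected by downstream variance-component models.
    """
    from .stability import pixel_stats

    if stack.n_years < 2:
        raise ValueError("need at least 2 years of the crop")
    _check_aligned(stability, stack.maps[0])
    _, sd = pixel_stats(stack)
    both = stack.joint_mask & stability.valid_mask
    crop = stack.maps[0].crop.value
    fid = field_id if field_id is not None else stack.field_id
    recs = []
    ii, jj = np.nonzero(both)
    for i, j in zip(ii.tolist(), jj.tolist()):
        recs.append(
            {
                "pixel": f"{i},{j}",
                "temporal_sd": float(sd[i, j]),
                "field": fid,
                "stability_class": CLASS_NAMES[int(stability.classes[i, j])],
                "crop": crop,
                "state": state,
                "farmer": farmer_id,
            }
        )
    table = pd.DataFrame(recs)
    by_class = {
        name: float(g["temporal_sd"].mean())
        for name, g in table.groupby("stability_class")
    }
    return by_class, table


def algorithm_contingency(map_sd: StabilityMap, map_two_way: StabilityMap) -> pd.DataFrame:
    """3x3 cross-tabulation of the two algorithms' classes, in percent.

    Rows are the SD-algorithm classes, columns the two-way classes; cells sum
    to 100 over the jointly valid pixels.  Maps must be three-class (no
    uncertain code).
    """
    if map_sd.shape != map_two_way.shape:
        raise ValueError("grid mismatch")
    for m in (map_sd, map_two_way):
        if (m.classes == 4).any():
            raise ValueError("contingency needs 3-class maps (no uncertain code)")
    both = map_sd.valid_mask & map_two_way.valid_mask
    n = int(both.sum())
    if n == 0:
        raise ValueError("no jointly valid pixels")
    names = [CLASS_NAMES[c] for c in _THREE_CLASSES]
    table = pd.DataFrame(0.0, index=names, columns=names)
    for ci in _THREE_CLASSES:
        for cj in _THREE_CLASSES:
            cnt = int((both & (map_sd.classes == ci) & (map_two_way.classes == cj)).sum())
            table.loc[CLASS_NAMES[ci], CLASS_NAMES[cj]] = 100.0 * cnt / n
    return table


def mean_contingency(
    tables: Sequence[pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unweighted mean and SD of per-field contingency tables, cell by cell."""
    if not tables:
        raise ValueError("no tables")
    cube = np.stack([t.to_numpy() for t in tables])
    ref = tables[0]
    mean = pd.DataFrame(cube.mean(axis=0), index=ref.index, columns=ref.columns)
    sd = pd.DataFrame(cube.std(axis=0, ddof=1), index=ref.index, columns=ref.columns)
    return mean, sd


def covariate_table(
    fields: Sequence[Mapping],
) -> pd.DataFrame:
    """Per-field covariates for the unstable-fraction model.

    Each entry needs keys ``stability`` (a StabilityMap), ``n_years``, and
    ``farmer_id``; ``rain_range_mm`` (wettest-year minus driest-year summer
    rain) is user-supplied and may be missing, in which case the row is
    flagged, not dropped.
    """
    rows = []
    for f in fields:
        smap: StabilityMap = f["stability"]
        fracs = class_fractions(smap)
        rain = f.get("rain_range_mm")
        rows.append(
            {
                "field": f.get("field_id", ""),
                "n_years_available": int(f["n_years"]),
                "unstable_fraction": fracs["unstable"],
                "rain_range_mm": np.nan if rain is None else float(rain),
                "farmer_id": f["farmer_id"],
                "missing_covariate": rain is None,
            }
        )
    return pd.DataFrame(rows)
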