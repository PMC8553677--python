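"""Per-map normalization and the two temporal yield-stability classifiers.

Both classifiers partition the pixels of a field into three classes across
years: *low-and-stable*, *high-and-stable*, and *unstable*.  Yield maps are
first normalized per map (z-scores: mean 0, SD 1 over valid pixels), so years
and crops with different absolute yield levels become comparable.

standard-deviation algorithm
    A pixel is unstable when the sample SD of its normalized yield across
    years exceeds ``sd_threshold`` (default 0.75); the remaining pixels split
    at ``mean_threshold`` (default 0.2) on the mean normalized yield
    (>= threshold is high-and-stable).

two-way outlier algorithm
    Each year's map is split into low / medium / high bands at the p-th and
    (1-p)-th within-map percentiles (default width p = 0.35).  A pixel seen in
    the low band in at least one year *and* the high band in at least one
    other year is unstable; the remaining pixels split on the mean normalized
    yield at ``mean_threshold`` (default 0.3).

Sample statistics use the n-1 denominator throughout; quantiles interpolate
linearly between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_core import (
    CLASS_HIGH_STABLE,
    CLASS_LOW_STABLE,
    CLASS_NODATA,
    CLASS_UNSTABLE,
    StabilityMap,
    YieldMap,
    YieldStack,
)

__all__ = [
    "ThresholdSet",
    "normalize_map",
    "pixel_stats",
    "classify_sd",
    "rank_categories",
    "classify_two_way",
    "classify",
    "map_agreement",
    "DEFAULT_SD_THRESHOLDS",
    "DEFAULT_TWO_WAY_THRESHOLDS",
]

RANK_LOW, RANK_MEDIUM, RANK_HIGH = -1, 0, 1


@dataclass(frozen=True)
class ThresholdSet:
    """Classifier parameters, in normalized-yield units.

    ``sd_threshold`` applies to the standard-deviation algorithm only;
    ``percentile_width`` (a proportion in (0, 0.5)) to the two-way algorithm
    only.
    """

    algorithm: str
    mean_threshold: float
    sd_threshold: float | None = None
    percentile_width: float | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ("sd", "two_way"):
            raise ValueError("algorithm must be 'sd' or 'two_way'")
        if self.algorithm == "sd":
            if self.sd_threshold is None or not self.sd_threshold > 0:
                raise ValueError("sd_threshold must be > 0")
        else:
            w = self.percentile_width
            if w is None or not 0.0 < w < 0.5:
                raise ValueError("percentile_width must lie in (0, 0.5)")


#: Calibrated defaults: mean 0.2 / SD 0.75 and mean 0.3 / width 0.35.
DEFAULT_SD_THRESHOLDS = ThresholdSet("sd", mean_threshold=0.2, sd_threshold=0.75)
DEFAULT_TWO_WAY_THRESHOLDS = ThresholdSet("two_way", mean_threshold=0.3, percentile_width=0.35)


def normalize_map(ymap: YieldMap) -> YieldMap:
    """Z-score a yield map over its valid pixels (mean 0, sample SD 1)."""
    vv = ymap.valid_values()
    if vv.size < 2:
        raise ValueError("need at least 2 valid pixels to normalize")
    sd = vv.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate map: zero spread, cannot normalize")
    out = ymap.copy()
    out.values = np.where(ymap.valid_mask, (ymap.values - vv.mean()) / sd, 0.0)
    out.normalized = True
    return out


def pixel_stats(stack: YieldStack) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and sample SD across years, NaN outside the joint mask."""
    cube = stack.data_cube()
    mean = cube.mean(axis=0)
    sd = cube.std(axis=0, ddof=1)
    mean[~stack.joint_mask] = np.nan
    sd[~stack.joint_mask] = np.nan
    return mean, sd


def classify_sd(
    stack: YieldStack, thresholds: ThresholdSet = DEFAULT_SD_THRESHOLDS
) -> StabilityMap:
    """Standard-deviation stability classification of a normalized stack."""
    if thresholds.algorithm != "sd":
        raise ValueError("thresholds are not for the sd algorithm")
    mean, sd = pixel_stats(stack)
    classes = np.full(stack.shape, CLASS_NODATA, dtype=np.uint8)
    jm = stack.joint_mask
    unstable = jm & (sd > thresholds.sd_threshold)
    high = jm & ~unstable & (mean >= thresholds.mean_threshold)
    low = jm & ~unstable & ~high
    classes[unstable] = CLASS_UNSTABLE
    classes[high] = CLASS_HIGH_STABLE
    classes[low] = CLASS_LOW_STABLE
    return StabilityMap(
        classes,
        transform=stack.transform,
        algorithm="sd",
        thresholds=thresholds,
        years=stack.years,
    )


def rank_categories(ymap: YieldMap, percentile_width: float = 0.35) -> np.ndarray:
    """Band a map's pixels into low / medium / high at within-map percentiles.

    Returns an integer grid with -1 (low, value < p-quantile), +1 (high,
    value > (1-p)-quantile), 0 (medium, or nodata — mask separately).
    Comparisons are strict, so a fully tied map is all medium.
    """
    if not 0.0 < percentile_width < 0.5:
        raise ValueError("percentile_width must lie in (0, 0.5)")
    vv = ymap.valid_values()
    if vv.size < 3:
        raise ValueError("need at least 3 valid pixels")
    q_low, q_high = np.quantile(vv, [percentile_width, 1.0 - percentile_width])
    ranks = np.zeros(ymap.shape, dtype=np.int8)
    ranks[ymap.valid_mask & (ymap.values < q_low)] = RANK_LOW
    ranks[ymap.valid_mask & (ymap.values > q_high)] = RANK_HIGH
    return ranks


def classify_two_way(
    stack: YieldStack, thresholds: ThresholdSet = DEFAULT_TWO_WAY_THRESHOLDS
) -> StabilityMap:
    """Two-way-outlier stability classification of a normalized stack.

    Percentile bands are computed per year over each map's own valid pixels,
    so band membership is invariant under any strictly increasing transform
    of a year's raw yields.
    """
    if thresholds.algorithm != "two_way":
        raise ValueError("thresholds are not for the two_way algorithm")
    jm = stack.joint_mask
    ever_low = np.zeros(stack.shape, dtype=bool)
    ever_high = np.zeros(stack.shape, dtype=bool)
    for m in stack.maps:
        ranks = rank_categories(m, thresholds.percentile_width)
        ever_low |= ranks == RANK_LOW
        ever_high |= ranks == RANK_HIGH
    mean, _ = pixel_stats(stack)
    classes = np.full(stack.shape, CLASS_NODATA, dtype=np.uint8)
    unstable = jm & ever_low & ever_high
    high = jm & ~unstable & (mean >= thresholds.mean_threshold)
    low = jm & ~unstable & ~high
    classes[unstable] = CLASS_UNSTABLE
    classes[high] = CLASS_HIGH_STABLE
    classes[low] = CLASS_LOW_STABLE
    return StabilityMap(
        classes,
        transform=stack.transform,
        algorithm="two_way",
        thresholds=thresholds,
        years=stack.years,
    )


def classify(stack: YieldStack, thresholds: ThresholdSet) -> StabilityMap:
    """Dispatch to the classifier named by ``thresholds.algorithm``."""
    if thresholds.algorithm == "sd":
        return classify_sd(stack, thresholds)
    return classify_two_way(stack, thresholds)


def map_agreement(a: StabilityMap, b: StabilityMap) -> float:
    """Fraction of jointly valid pixels given the same class by two maps."""
    if a.shape != b.shape:
        raise ValueError("grid mismatch")
    both = a.valid_mask & b.valid_mask
    n = int(both.sum())
    if n == 0:
        raise ValueError("no jointly valid pixel")
    return float((a.classes[both] == b.classes[both]).sum() / n)
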