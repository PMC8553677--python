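"""Independent, naively-looped reference implementations used as test oracles.

Deliberately written with plain Python loops and the statistics module where
possible, sharing no code path with the package.
"""

from __future__ import annotations

import math
import statistics


def sample_sd(xs) -> float:
    return statistics.stdev(xs)


def linear_quantile(sorted_vals, p: float) -> float:
    """Linear-interpolation quantile of pre-sorted values (R type-7)."""
    n = len(sorted_vals)
    h = (n - 1) * p
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def classify_sd_pixel(series, mean_thr: float, sd_thr: float) -> int:
    """SD-algorithm class of one pixel's normalized year series.

    Returns the package's class codes: 1 low, 2 high, 3 unstable.
    """
    if sample_sd(series) > sd_thr:
        return 3
    return 2 if statistics.fmean(series) >= mean_thr else 1


def classify_two_way_stack(year_values, mean_thr: float, width: float):
    """Two-way classes for a stack given as list-of-years of per-pixel values.

    ``year_values[t]`` is a list of (pixel_key, value) for year t's valid
    pixels; classification covers pixels present in every year.  Returns a
    dict pixel_key -> class code.
    """
    bands_per_year = []
    for pairs in year_values:
        vals = sorted(v for _, v in pairs)
        q_low = linear_quantile(vals, width)
        q_high = linear_quantile(vals, 1.0 - width)
        bands = {}
        for key, v in pairs:
            bands[key] = -1 if v < q_low else (1 if v > q_high else 0)
        bands_per_year.append(bands)
    common = set(bands_per_year[0])
    for b in bands_per_year[1:]:
        common &= set(b)
    out = {}
    for key in common:
        seq = [b[key] for b in bands_per_year]
        if -1 in seq and 1 in seq:
            out[key] = 3
            continue
        series = [dict(pairs)[key] for pairs in year_values]
        out[key] = 2 if statistics.fmean(series) >= mean_thr else 1
    return out


def skewness_oracle(xs) -> float:
    n = len(xs)
    mean = sum(xs) / n
    m2 = sum((x - mean) ** 2 for x in xs) / n
    m3 = sum((x - mean) ** 3 for x in xs) / n
    return m3 / m2**1.5


def pearson_r(xs, ys) -> float:
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den
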