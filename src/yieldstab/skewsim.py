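"""Skewness diagnostics and the skewed-matrix simulation.

Within-field yield distributions are typically left-skewed (a long tail of
poor pixels).  When per-pixel yearly yields are drawn from a skewed
distribution, the per-pixel mean and SD across years become correlated, with
the sign of the correlation following the sign of the skew: under left skew
the low-mean pixels are the ones that occasionally crash, so they also have
the larger SDs and the mean-SD correlation is negative.  This module provides
the skewness statistic, the per-field mean-SD correlation diagnostic, and a
Monte-Carlo simulation of that mechanism using the skew-normal family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .raster_core import YieldStack

__all__ = ["SkewSimSpec", "skewness", "mean_sd_correlation", "simulate_skew_matrix"]


@dataclass(frozen=True)
class SkewSimSpec:
    """Parameters of the skewed-matrix simulation.

    Rows of the simulated matrix are pixels, columns are years; each column
    is an i.i.d. draw from skew-normal(location, scale, shape).  A negative
    shape gives left skew.
    """

    n_pixels: int
    n_years: int = 10
    shape: float = -5.0
    location: float = 0.0
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pixels < 10:
            raise ValueError("n_pixels must be >= 10")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")


def skewness(values: np.ndarray) -> float:
    """Fisher-Pearson moment skewness g1 = m3 / m2^{3/2}.

    Population moments (divide by n): m_k = sum((x - mean)^k) / n.  Requires
    at least 3 values and nonzero variance.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 values")
    d = x - x.mean()
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        raise ValueError("constant sample: skewness undefined")
    m3 = float(np.mean(d**3))
    return m3 / m2**1.5


@dataclass
class MeanSdCorrelation:
    r: float
    slope: float
    intercept: float
    n_pixels: int
    defined: bool = True


def mean_sd_correlation(stack: YieldStack) -> MeanSdCorrelation:
    """Pearson correlation of per-pixel mean vs per-pixel SD across years.

    Also returns the OLS slope/intercept of SD regressed on mean (the
    single-field version of the pooled mean-variability regression).  With
    zero variance in either axis the correlation is undefined and flagged.
    """
    from .stability import pixel_stats

    if stack.n_years < 3:
        raise ValueError("need at least 3 years")
    mean, sd = pixel_stats(stack)
    m = mean[stack.joint_mask]
    s = sd[stack.joint_mask]
    if m.size < 3:
        raise ValueError("need at least 3 valid pixels")
    if np.ptp(m) == 0.0 or np.ptp(s) == 0.0:
        return MeanSdCorrelation(np.nan, np.nan, np.nan, m.size, defined=False)
    r = float(np.corrcoef(m, s)[0, 1])
    slope, intercept = np.polyfit(m, s, 1)
    return MeanSdCorrelation(r, float(slope), float(intercept), m.size)


def simulate_skew_matrix(
    spec: SkewSimSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Simulate the pixels-by-years matrix and its row mean-SD correlation.

    Returns (matrix, row means, row sample SDs, Pearson r between them).
    Seeded and reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    m = stats.skewnorm.rvs(
        spec.shape,
        loc=spec.location,
        scale=spec.scale,
        size=(spec.n_pixels, spec.n_years),
        random_state=rng,
    )
    means = m.mean(axis=1)
    sds = m.std(axis=1, ddof=1)
    r = float(np.corrcoef(means, sds)[0, 1])
    return m, means, sds, r
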