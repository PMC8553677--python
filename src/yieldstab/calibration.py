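"""Threshold calibration by maximizing stability-map repeatability.

Any particular set of harvest years a farmer holds is a sample of all
possible years, so good thresholds are those that make the stability map
*repeatable*: splitting a field's years into two disjoint sets should produce
two near-identical maps.  The calibration enumerates all such two-block year
splits, samples fields and splits, and runs a Nelder–Mead simplex search over
the two classifier parameters, maximizing the mean pixelwise agreement
between the maps built from the two sides of each field's split.  Repeating
the search over many random field subsets yields a distribution of optima
summarized by the componentwise median.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence
import warnings

import numpy as np
from scipy.optimize import minimize

from .raster_core import YieldStack
from .stability import ThresholdSet, classify, map_agreement

__all__ = [
    "YearSplit",
    "OptimizationResult",
    "enumerate_splits",
    "repeatability_objective",
    "optimize_thresholds",
    "grid_search_objective",
    "SEARCH_BOUNDS",
]

# Box constraints on the searched parameters (normalized-yield units for the
# thresholds, proportion for the percentile width).
SEARCH_BOUNDS = {
    "mean_threshold": (-1.0, 1.0),
    "sd_threshold": (0.05, 3.0),
    "percentile_width": (0.05, 0.49),
}


@dataclass(frozen=True)
class YearSplit:
    """A two-block partition of a field's available years."""

    set_a: tuple[int, ...]
    set_b: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.set_a) & set(self.set_b):
            raise ValueError("split sides must be disjoint")


@dataclass
class OptimizationResult:
    """All per-repetition optima plus the componentwise median summary."""

    algorithm: str
    samples: list[tuple[float, float]]
    objective_at_optimum: list[float]
    seed: int

    @property
    def median_thresholds(self) -> ThresholdSet:
        arr = np.asarray(self.samples)
        med = np.median(arr, axis=0)
        if self.algorithm == "sd":
            return ThresholdSet("sd", mean_threshold=float(med[0]), sd_threshold=float(med[1]))
        return ThresholdSet(
            "two_way", mean_threshold=float(med[0]), percentile_width=float(med[1])
        )


def enumerate_splits(years: Sequence[int], min_set_years: int = 3) -> list[YearSplit]:
    """All unordered two-block partitions with both blocks >= ``min_set_years``.

    The two orderings of one partition (a|b and b|a) count once; for an even
    split of all years, each unordered pair appears exactly once.
    """
    years = sorted(set(years))
    n = len(years)
    if n < 2 * min_set_years:
        raise ValueError(
            f"need at least {2 * min_set_years} years to split, got {n}"
        )
    splits: list[YearSplit] = []
    anchor = years[0]  # fixing the first year on side a kills the a|b ~ b|a duplicate
    rest = years[1:]
    for k in range(min_set_years - 1, n - min_set_years + 1):
        for combo in combinations(rest, k):
            set_a = (anchor, *combo)
            set_b = tuple(y for y in years if y not in set_a)
            if len(set_b) >= min_set_years:
                splits.append(YearSplit(set_a, set_b))
    return splits


def _vector_to_thresholds(x: np.ndarray, algorithm: str) -> ThresholdSet:
    if algorithm == "sd":
        return ThresholdSet("sd", mean_threshold=float(x[0]), sd_threshold=float(x[1]))
    return ThresholdSet("two_way", mean_threshold=float(x[0]), percentile_width=float(x[1]))


def _param_bounds(algorithm: str) -> list[tuple[float, float]]:
    second = "sd_threshold" if algorithm == "sd" else "percentile_width"
    return [SEARCH_BOUNDS["mean_threshold"], SEARCH_BOUNDS[second]]


def repeatability_objective(
    fields: Sequence[tuple[YieldStack, YearSplit]], thresholds: ThresholdSet
) -> float:
    """Mean over fields of the agreement between the two split-side maps."""
    if not fields:
        raise ValueError("no fields")
    agreements = []
    for stack, split in fields:
        map_a = classify(stack.subset(split.set_a), thresholds)
        map_b = classify(stack.subset(split.set_b), thresholds)
        agreements.append(map_agreement(map_a, map_b))
    return float(np.mean(agreements))


def _objective_vector(
    x: np.ndarray, fields, algorithm: str, lo: np.ndarray, hi: np.ndarray
) -> float:
    x = np.clip(x, lo, hi)
    return -repeatability_objective(fields, _vector_to_thresholds(x, algorithm))


def optimize_thresholds(
    dataset: Sequence[YieldStack],
    algorithm: str = "sd",
    n_reps: int = 600,
    fields_per_rep: int = 30,
    seed: int = 0,
    min_years: int = 6,
    min_set_years: int = 3,
    start: ThresholdSet | None = None,
    max_iter: int = 200,
) -> OptimizationResult:
    """Repeated simplex calibration of the stability thresholds.

    Each repetition samples ``fields_per_rep`` fields (with at least
    ``min_years`` years each; with replacement when the eligible pool is
    smaller), draws one calibration-validation year split per field uniformly
    from all admissible splits, and maximizes the repeatability objective by
    Nelder-Mead from the published default thresholds.  The best point
    *evaluated* during each search is recorded, so a repetition can never
    report a vertex worse than its start.  Fully reproducible given ``seed``.
    """
    eligible = [s for s in dataset if s.n_years >= min_years]
    if not eligible:
        raise ValueError(f"no field with at least {min_years} years")
    if len(eligible) < fields_per_rep:
        warnings.warn(
            f"only {len(eligible)} eligible fields for {fields_per_rep} per repetition; "
            "sampling with replacement",
            stacklevel=2,
        )
    replace = len(eligible) < fields_per_rep
    splits_per_field = [enumerate_splits(s.years, min_set_years) for s in eligible]

    if start is None:
        start = (
            ThresholdSet("sd", 0.2, sd_threshold=0.75)
            if algorithm == "sd"
            else ThresholdSet("two_way", 0.3, percentile_width=0.35)
        )
    x0 = np.array(
        [
            start.mean_threshold,
            start.sd_threshold if algorithm == "sd" else start.percentile_width,
        ]
    )
    bounds = _param_bounds(algorithm)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    rng = np.random.default_rng(seed)
    samples: list[tuple[float, float]] = []
    objectives: list[float] = []
    for _ in range(n_reps):
        idx = rng.choice(len(eligible), size=fields_per_rep, replace=replace)
        fields = []
        for i in idx:
            split = splits_per_field[i][rng.integers(len(splits_per_field[i]))]
            fields.append((eligible[i], split))

        best = {"x": np.clip(x0, lo, hi), "f": None}

        def tracked(x, _fields=fields, _best=best):
            f = _objective_vector(x, _fields, algorithm, lo, hi)
            if _best["f"] is None or f < _best["f"]:
                _best["f"] = f
                _best["x"] = np.clip(x, lo, hi)
            return f

        def run_simplex(start_x):
            # wide initial simplex (half the box per coordinate): the
            # agreement surface has competing ridges and a tiny default
            # simplex stalls on the first one it touches
            simplex = np.array([start_x, start_x, start_x], dtype=float)
            for d in range(2):
                step = 0.5 * (hi[d] - lo[d])
                simplex[d + 1, d] = (
                    start_x[d] + step if start_x[d] + step <= hi[d] else start_x[d] - step
                )
            minimize(
                tracked,
                start_x,
                method="Nelder-Mead",
                bounds=bounds,
                options={
                    "maxiter": max_iter,
                    "fatol": 1e-4,
                    "xatol": 1e-4,
                    "initial_simplex": simplex,
                },
            )

        run_simplex(x0)
        # the simplex is a local method and the agreement surface is
        # multimodal (degenerate one-class maps agree trivially), so screen a
        # coarse lattice of alternative starts; ties go to the point nearest
        # the published prior, since the objective is flat across a
        # degenerate optimum
        lattice = [
            np.array([a, b])
            for a in np.linspace(lo[0], hi[0], 5)
            for b in np.linspace(lo[1], hi[1], 5)
        ]
        lattice.sort(key=lambda p: float(np.linalg.norm(p - x0)))
        vals = [_objective_vector(p, fields, algorithm, lo, hi) for p in lattice]
        k_best = int(np.argmin(vals))  # first minimum = nearest-to-prior tie-break
        if vals[k_best] < best["f"] - 1e-12:
            best["f"], best["x"] = vals[k_best], lattice[k_best]
            run_simplex(lattice[k_best])
        samples.append((float(best["x"][0]), float(best["x"][1])))
        objectives.append(-best["f"])
    return OptimizationResult(algorithm, samples, objectives, seed)


def grid_search_objective(
    fields: Sequence[tuple[YieldStack, YearSplit]],
    algorithm: str,
    n_grid: int = 11,
) -> tuple[ThresholdSet, float]:
    """Exhaustive grid evaluation of the repeatability objective.

    An independent coarse check on the simplex search: evaluates the same
    objective on an ``n_grid`` x ``n_grid`` lattice over the search box and
    returns the best cell.
    """
    bounds = _param_bounds(algorithm)
    g1 = np.linspace(*bounds[0], n_grid)
    g2 = np.linspace(*bounds[1], n_grid)
    best_thr, best_obj = None, -np.inf
    for a in g1:
        for b in g2:
            thr = _vector_to_thresholds(np.array([a, b]), algorithm)
            obj = repeatability_objective(fields, thr)
            if obj > best_obj:
                best_obj, best_thr = obj, thr
    return best_thr, float(best_obj)
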