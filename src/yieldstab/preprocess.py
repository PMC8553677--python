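"""Yield-monitor point cleaning and point-to-raster interpolation.

Raw combine-monitor data arrive as projected points (x, y in meters, yield in
Mg/ha).  The pipeline is: median-based outlier filtering (keep yields within
0.1x and 3x the crop median), dissolution of exact coordinate duplicates to
their mean yield, ordinary kriging onto a fine grid with a spherical
semivariogram, fixed 20 m search radius and a minimum of 12 neighbors, then
block aggregation to the working resolution (2 m -> 30 m by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .raster_core import Crop, GridTransform, YieldMap

__all__ = [
    "PointSet",
    "VariogramModel",
    "read_points",
    "write_points",
    "filter_outlier_points",
    "dissolve_duplicates",
    "fit_variogram",
    "krige_spherical",
    "aggregate_blocks",
]

logger = logging.getLogger(__name__)


@dataclass
class PointSet:
    """Cleaned yield-monitor points: parallel x, y (m) and yield (Mg/ha)."""

    x: np.ndarray
    y: np.ndarray
    yields: np.ndarray
    crop: Crop = Crop.OTHER

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)
        if not (self.x.shape == self.y.shape == self.yields.shape) or self.x.ndim != 1:
            raise ValueError("x, y, yields must be parallel 1-D sequences")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite coordinate")
        self.crop = Crop(self.crop)

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class VariogramModel:
    """Spherical semivariogram: gamma(h) = nugget + psill * sph(h / range)."""

    nugget: float
    partial_sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_m <= 0:
            raise ValueError("need nugget >= 0, partial_sill >= 0, range_m > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        r = np.clip(h / self.range_m, 0.0, 1.0)
        gamma = self.nugget + self.partial_sill * (1.5 * r - 0.5 * r**3)
        # gamma(0) = 0 exactly: the nugget acts only between distinct points,
        # keeping kriging an exact interpolator in the zero-nugget limit.
        return np.where(h == 0.0, 0.0, gamma)


def read_points(path: str | Path, crop: Crop | str = Crop.OTHER) -> PointSet:
    """Read delimited text with columns x, y, yield (comma or tab, header required)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        return PointSet(
            df[cols["x"]].to_numpy(),
            df[cols["y"]].to_numpy(),
            df[cols["yield"]].to_numpy(),
            crop=Crop(crop),
        )
    except KeyError as exc:
        raise ValueError(f"points file needs columns x, y, yield; got {list(df.columns)}") from exc


def write_points(path: str | Path, points: PointSet) -> None:
    pd.DataFrame({"x": points.x, "y": points.y, "yield": points.yields}).to_csv(
        path, index=False
    )


def filter_outlier_points(
    points: PointSet, low_factor: float = 0.1, high_factor: float = 3.0
) -> tuple[PointSet, int]:
    """Drop yields outside [low_factor, high_factor] x the median of the input set.

    Returns the retained points and the number removed.
    """
    if len(points) == 0:
        raise ValueError("empty point set")
    med = float(np.median(points.yields))
    keep = (points.yields >= low_factor * med) & (points.yields <= high_factor * med)
    removed = int((~keep).sum())
    return (
        PointSet(points.x[keep], points.y[keep], points.yields[keep], points.crop),
        removed,
    )


def dissolve_duplicates(points: PointSet) -> PointSet:
    """Collapse points sharing exact (x, y) into one point with the mean yield."""
    coords = np.column_stack([points.x, points.y])
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if uniq.shape[0] == len(points):
        return replace(points)
    sums = np.bincount(inverse, weights=points.yields)
    counts = np.bincount(inverse)
    return PointSet(uniq[:, 0], uniq[:, 1], sums / counts, points.crop)


def _spherical(h: np.ndarray, nugget: float, psill: float, rng: float) -> np.ndarray:
    r = np.clip(h / rng, 0.0, 1.0)
    return nugget + psill * (1.5 * r - 0.5 * r**3)


def fit_variogram(
    points: PointSet, n_lags: int = 15, max_dist_m: float = 200.0
) -> VariogramModel:
    """Fit a spherical model to the empirical semivariogram.

    Pairs up to ``max_dist_m`` apart are binned into ``n_lags`` equal-width
    distance classes; the model is fitted by least squares weighted by pair
    counts, with nugget and partial sill constrained non-negative.
    """
    if len(points) < 30:
        raise ValueError("need at least 30 points to fit a variogram")
    coords = np.column_stack([points.x, points.y])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(max_dist_m, output_type="ndarray")
    if pairs.size == 0:
        raise ValueError("no point pairs within max_dist_m")
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    sq = 0.5 * (points.yields[pairs[:, 0]] - points.yields[pairs[:, 1]]) ** 2
    edges = np.linspace(0.0, max_dist_m, n_lags + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_lags - 1)
    counts = np.bincount(which, minlength=n_lags)
    ok = counts > 0
    if not ok.any():
        raise ValueError("too few pairs in every lag")
    gamma = np.bincount(which, weights=sq, minlength=n_lags)[ok] / counts[ok]
    centers = (0.5 * (edges[:-1] + edges[1:]))[ok]
    w = np.sqrt(counts[ok].astype(float))

    total_var = float(points.yields.var())
    if total_var == 0.0:
        return VariogramModel(0.0, 0.0, max(max_dist_m / 4, 1.0))

    def resid(theta):
        nug, psill, rng = theta
        return w * (_spherical(centers, nug, psill, rng) - gamma)

    x0 = np.array([gamma[0] / 2, max(total_var - gamma[0] / 2, 1e-6), max_dist_m / 3])
    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 10 * max_dist_m]),
    )
    nug, psill, rng = sol.x
    return VariogramModel(float(nug), float(psill), float(rng))


def krige_spherical(
    points: PointSet,
    grid: GridTransform | None = None,
    variogram: VariogramModel | None = None,
    radius_m: float = 20.0,
    min_points: int = 12,
    pixel_m: float = 2.0,
    field_id: str = "",
    year: int = 0,
    shape: tuple[int, int] | None = None,
) -> YieldMap:
    """Ordinary kriging of the points onto a regular grid.

    Each cell center is predicted from the neighbors within ``radius_m``;
    cells with fewer than ``min_points`` neighbors become nodata.  Ordinary
    kriging constrains the weights to sum to 1 via a Lagrange multiplier, so
    a constant field is reproduced exactly and predictions are equivariant
    under adding a constant to all yields.  Exact-duplicate neighbors are
    collapsed before solving; a singular system is logged and yields nodata.
    """
    if len(points) == 0:
        raise ValueError("empty point set")
    pts = dissolve_duplicates(points)
    if variogram is None:
        variogram = fit_variogram(pts)
    if grid is None:
        grid = GridTransform(
            x_ll=float(pts.x.min()), y_ll=float(pts.y.min()), pixel_size=pixel_m
        )
    if shape is None:
        ncols = max(int(np.ceil((pts.x.max() - grid.x_ll) / grid.pixel_size)), 1)
        nrows = max(int(np.ceil((pts.y.max() - grid.y_ll) / grid.pixel_size)), 1)
        shape = (nrows, ncols)
    nrows, ncols = shape

    coords = np.column_stack([pts.x, pts.y])
    tree = cKDTree(coords)
    # cell centers; row 0 is the northernmost row
    cx = grid.x_ll + (np.arange(ncols) + 0.5) * grid.pixel_size
    cy = grid.y_ll + (np.arange(nrows)[::-1] + 0.5) * grid.pixel_size

    values = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    for i in range(nrows):
        for j in range(ncols):
            center = np.array([cx[j], cy[i]])
            idx = tree.query_ball_point(center, radius_m)
            if len(idx) < min_points:
                continue
            idx = np.asarray(idx)
            nb = coords[idx]
            z = pts.yields[idx]
            n = len(idx)
            d_nn = np.linalg.norm(nb[:, None, :] - nb[None, :, :], axis=-1)
            d_n0 = np.linalg.norm(nb - center, axis=1)
            a = np.empty((n + 1, n + 1))
            a[:n, :n] = variogram(d_nn)
            a[n, :] = 1.0
            a[:, n] = 1.0
            a[n, n] = 0.0
            b = np.append(variogram(d_n0), 1.0)
            try:
                w = np.linalg.solve(a, b)
            except np.linalg.LinAlgError:
                logger.warning("singular kriging system at cell (%d, %d); nodata", i, j)
                continue
            values[i, j] = float(w[:n] @ z)
            mask[i, j] = True
    if not mask.any():
        warnings.warn("kriging produced an empty map (no cell met min_points)", stacklevel=2)
    return YieldMap(values, mask, field_id=field_id, year=year, crop=pts.crop, transform=grid)


def aggregate_blocks(
    ymap: YieldMap, factor: int = 15, min_valid_fraction: float = 0.5
) -> YieldMap:
    """Block-mean aggregation to a coarser grid (default 2 m -> 30 m).

    Each output cell is the mean of the valid input cells in its
    ``factor x factor`` block and is nodata when fewer than
    ``min_valid_fraction`` of the block's cells are valid.  Partial blocks at
    the south/east edges are judged against their actual size.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return ymap.copy()
    nrows, ncols = ymap.shape
    out_r = int(np.ceil(nrows / factor))
    out_c = int(np.ceil(ncols / factor))
    values = np.zeros((out_r, out_c))
    mask = np.zeros((out_r, out_c), dtype=bool)
    for i in range(out_r):
        for j in range(out_c):
            blk_v = ymap.values[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            blk_m = ymap.valid_mask[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            if blk_m.sum() >= min_valid_fraction * blk_m.size and blk_m.any():
                values[i, j] = blk_v[blk_m].mean()
                mask[i, j] = True
    t = ymap.transform
    # anchor the lower-left corner so the footprint origin is preserved
    new_t = GridTransform(
        x_ll=t.x_ll,
        y_ll=t.y_ll + (nrows - out_r * factor) * t.pixel_size,
        pixel_size=t.pixel_size * factor,
    )
    return YieldMap(
        values, mask, field_id=ymap.field_id, year=ymap.year, crop=ymap.crop, transform=new_t
    )
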