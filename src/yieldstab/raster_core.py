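"""Yield-map data model and grid I/O.

A :class:`YieldMap` is one field-year-crop raster of yield values (Mg/ha) on a
regular square grid, with an explicit boolean validity mask — nodata never
appears as a sentinel value inside computations.  A :class:`YieldStack` is an
aligned multi-year collection of *normalized* maps for one field, the input of
the stability classifiers.  A :class:`StabilityMap` is the categorical result.

Grid convention: row 0 is the northernmost row, pixel coordinates are 0-based,
and a cell value refers to the full cell.  On disk the package reads and writes
the ESRI ASCII grid format (a plain-text header followed by the value matrix),
which round-trips values, mask and geometry losslessly at float64 precision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Crop",
    "GridTransform",
    "YieldMap",
    "YieldStack",
    "StabilityMap",
    "CLASS_NODATA",
    "CLASS_LOW_STABLE",
    "CLASS_HIGH_STABLE",
    "CLASS_UNSTABLE",
    "CLASS_UNCERTAIN",
    "CLASS_NAMES",
    "read_yield_map",
    "write_yield_map",
    "read_class_map",
    "write_class_map",
    "passes_coverage_filter",
    "build_stack",
]

# Fixed class codes so rasters written by different runs compare bit-exactly.
CLASS_NODATA = 0
CLASS_LOW_STABLE = 1
CLASS_HIGH_STABLE = 2
CLASS_UNSTABLE = 3
CLASS_UNCERTAIN = 4

CLASS_NAMES = {
    CLASS_NODATA: "nodata",
    CLASS_LOW_STABLE: "low_stable",
    CLASS_HIGH_STABLE: "high_stable",
    CLASS_UNSTABLE: "unstable",
    CLASS_UNCERTAIN: "uncertain",
}


class Crop(str, enum.Enum):
    MAIZE = "maize"
    SOYBEAN = "soybean"
    WHEAT = "wheat"
    COTTON = "cotton"
    OTHER = "other"


@dataclass(frozen=True)
class GridTransform:
    """Grid geometry: origin of the lower-left corner and square pixel size.

    ``x_ll``/``y_ll`` are projected meter coordinates of the lower-left corner
    of the lower-left cell (the ESRI ASCII convention); ``pixel_size`` is the
    cell edge in meters.
    """

    x_ll: float = 0.0
    y_ll: float = 0.0
    pixel_size: float = 30.0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel size must be > 0")

    def matches(self, other: "GridTransform", tol: float = 1e-9) -> bool:
        return (
            abs(self.x_ll - other.x_ll) <= tol
            and abs(self.y_ll - other.y_ll) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )


@dataclass
class YieldMap:
    """One field-year-crop yield raster with an explicit validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    field_id: str
    year: int
    crop: Crop = Crop.OTHER
    transform: GridTransform = field(default_factory=GridTransform)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        self.crop = Crop(self.crop)
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite value inside valid_mask")
        if self.normalized and self.n_valid >= 2:
            vv = self.values[self.valid_mask]
            if abs(vv.mean()) > 1e-9 or abs(vv.std(ddof=1) - 1.0) > 1e-9:
                raise ValueError("normalized flag set but values are not z-scores")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def copy(self) -> "YieldMap":
        return replace(self, values=self.values.copy(), valid_mask=self.valid_mask.copy())


@dataclass
class YieldStack:
    """Aligned, year-ordered stack of normalized maps for one field.

    ``joint_mask`` marks pixels valid in *every* member year; both classifiers
    need the full year series, so classification is restricted to it.
    """

    maps: list[YieldMap]
    joint_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.maps) < 2:
            raise ValueError("a stack needs at least 2 maps")
        self.joint_mask = np.logical_and.reduce([m.valid_mask for m in self.maps])

    @property
    def years(self) -> list[int]:
        return [m.year for m in self.maps]

    @property
    def field_id(self) -> str:
        return self.maps[0].field_id

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps[0].shape

    @property
    def transform(self) -> GridTransform:
        return self.maps[0].transform

    @property
    def n_years(self) -> int:
        return len(self.maps)

    def data_cube(self) -> np.ndarray:
        """(n_years, rows, cols) array; NaN outside each map's mask."""
        cube = np.full((self.n_years, *self.shape), np.nan)
        for k, m in enumerate(self.maps):
            cube[k][m.valid_mask] = m.values[m.valid_mask]
        return cube

    def subset(self, years: Sequence[int]) -> "YieldStack":
        """Sub-stack restricted to the given years (order by year preserved)."""
        wanted = set(years)
        missing = wanted - set(self.years)
        if missing:
            raise ValueError(f"years not in stack: {sorted(missing)}")
        return YieldStack([m for m in self.maps if m.year in wanted])


@dataclass
class StabilityMap:
    """Per-pixel categorical raster over the fixed stability class codes."""

    classes: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)
    algorithm: str = ""
    thresholds: object = None
    years: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.ndim != 2:
            raise ValueError("classes must be a 2-D grid")
        if not np.isin(self.classes, list(CLASS_NAMES)).all():
            raise ValueError("unknown class code")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.classes != CLASS_NODATA

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape


# ---------------------------------------------------------------------------
# ASCII-grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, np.ndarray, GridTransform]:
    lines = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
    return _parse_ascii_grid_lines(lines, path)


def _parse_ascii_grid_lines(
    lines: list[str], origin: Path
) -> tuple[np.ndarray, np.ndarray, GridTransform]:
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid missing header key {key!r}: {origin}")
    nodata = header.get("nodata_value", -9999.0)
    body = " ".join(lines[i:]).split()
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if len(body) != nrows * ncols:
        raise ValueError(f"ASCII grid body has {len(body)} values, expected {nrows * ncols}")
    grid = np.array(body, dtype=float).reshape(nrows, ncols)
    mask = (grid != nodata) & np.isfinite(grid)
    transform = GridTransform(
        x_ll=header.get("xllcorner", 0.0),
        y_ll=header.get("yllcorner", 0.0),
        pixel_size=header["cellsize"],
    )
    return grid, mask, transform


def _write_ascii_grid(
    path: Path,
    values: np.ndarray,
    mask: np.ndarray,
    transform: GridTransform,
    nodata: float = -9999.0,
    fmt: str = "%.17g",
) -> None:
    out = np.where(mask, values, nodata)
    nrows, ncols = out.shape
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {transform.x_ll:.17g}\nyllcorner {transform.y_ll:.17g}\n"
            f"cellsize {transform.pixel_size:.17g}\nNODATA_value {nodata:g}\n"
        )
        np.savetxt(fh, out, fmt=fmt)


def read_yield_map(
    path: str | Path,
    field_id: str,
    year: int,
    crop: Crop | str = Crop.OTHER,
) -> YieldMap:
    """Read a single-band ASCII-grid raster into a :class:`YieldMap`.

    Nodata cells (the header's ``NODATA_value``) are excluded from the valid
    mask.  Values are taken as Mg/ha as-is.  An all-nodata grid is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    grid, mask, transform = _read_ascii_grid(path)
    if not mask.any():
        raise ValueError(f"empty map: {path} has no valid pixels")
    return YieldMap(grid, mask, field_id=field_id, year=year, crop=Crop(crop), transform=transform)


def write_yield_map(path: str | Path, ymap: YieldMap, nodata: float = -9999.0) -> None:
    """Write a :class:`YieldMap` as an ESRI ASCII grid (lossless round-trip)."""
    _write_ascii_grid(Path(path), ymap.values, ymap.valid_mask, ymap.transform, nodata)


def write_class_map(path: str | Path, smap: StabilityMap) -> None:
    """Write a stability map as an integer ASCII grid; nodata is class code 0."""
    with open(path, "w") as fh:
        nrows, ncols = smap.shape
        t = smap.transform
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {t.x_ll:.17g}\nyllcorner {t.y_ll:.17g}\n"
            f"cellsize {t.pixel_size:.17g}\nNODATA_value 0\n"
        )
        fh.write(f"# classes: {'; '.join(f'{c}={n}' for c, n in CLASS_NAMES.items())}\n")
        np.savetxt(fh, smap.classes, fmt="%d")


def read_class_map(path: str | Path) -> StabilityMap:
    grid, _, transform = _read_ascii_grid(Path(path))
    return StabilityMap(grid.astype(np.uint8), transform=transform)


def passes_coverage_filter(
    ymap: YieldMap,
    max_missing_fraction: float = 0.25,
    footprint: np.ndarray | None = None,
) -> bool:
    """Map-level coverage filter: keep maps missing at most a quarter of the field.

    The missing fraction is computed within the field footprint (the full
    raster extent when no footprint mask is supplied).  The rule excludes maps
    missing *more than* ``max_missing_fraction`` of their data, so the boundary
    case (exactly 25% missing) passes.
    """
    if footprint is None:
        footprint = np.ones(ymap.shape, dtype=bool)
    footprint = np.asarray(footprint, dtype=bool)
    if footprint.shape != ymap.shape:
        raise ValueError("footprint shape differs from map shape")
    n_total = int(footprint.sum())
    if n_total == 0:
        raise ValueError("empty footprint")
    n_missing = n_total - int((ymap.valid_mask & footprint).sum())
    return n_missing / n_total <= max_missing_fraction


def build_stack(maps: Sequence[YieldMap]) -> YieldStack:
    """Assemble normalized per-year maps into a :class:`YieldStack`.

    Maps are ordered by year; all must share one grid and field id and carry
    the normalized flag.  A duplicate year is an error (one yield map per
    field, year and crop — multi-crop years are excluded upstream, never
    averaged here).
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    ref = maps[0]
    for m in maps:
        if m.field_id != ref.field_id:
            raise ValueError("field_id mismatch")
        if m.shape != ref.shape or not m.transform.matches(ref.transform):
            raise ValueError("grid mismatch")
        if not m.normalized:
            raise ValueError(f"map for year {m.year} is not normalized")
    years = [m.year for m in maps]
    if len(set(years)) != len(years):
        dup = sorted({y for y in years if years.count(y) > 1})
        raise ValueError(f"duplicate year in stack: {dup}")
    return YieldStack(sorted(maps, key=lambda m: m.year))
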