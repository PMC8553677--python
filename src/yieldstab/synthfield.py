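"""Synthetic multi-year yield fields with known ground-truth stability zones.

Real multi-year yield-monitor archives are farmer-private, so the package
ships a generator that emulates their salient structure: spatially coherent
latent zones (stable-high, stable-low, and weather-sensitive unstable areas),
a scalar per-year weather effect that the unstable zone responds to far more
strongly than the stable zones, and left-skewed pixel noise mimicking the
typical within-map yield distribution.  Because the truth (the planted zone
map) is known, classifier accuracy, threshold calibration and the voting
procedure are all testable offline.

The spatial zones come from thresholding a smoothed Gaussian white-noise
surface at the quantiles of the requested zone fractions, which yields
contiguous patches resembling real management zones.  Weather enters
linearly and uniformly across the field (fields are at most a couple of
kilometers wide, so no within-field weather gradient is modeled).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .raster_core import (
    CLASS_HIGH_STABLE,
    CLASS_LOW_STABLE,
    CLASS_UNSTABLE,
    Crop,
    GridTransform,
    YieldMap,
    YieldStack,
    build_stack,
    write_yield_map,
)
from .stability import normalize_map

__all__ = ["SyntheticFieldSpec", "SyntheticField", "generate_field", "generate_dataset"]

_CROP_ROTATION = (Crop.MAIZE, Crop.SOYBEAN, Crop.WHEAT)
# plausible raw scales per crop (Mg/ha): mean level and pixel-to-pixel SD
_CROP_SCALE = {
    Crop.MAIZE: (9.5, 1.8),
    Crop.SOYBEAN: (3.2, 0.6),
    Crop.WHEAT: (4.5, 0.9),
    Crop.COTTON: (1.2, 0.25),
    Crop.OTHER: (5.0, 1.0),
}


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Generator parameters; defaults are the strong-signal study conditions.

    Base levels are in normalized-yield units; the unstable zone sits at the
    field mean with a weather sensitivity an order of magnitude above the
    stable zones', so its relative performance is driven by the year effect
    while the stable zones' is not.
    """

    n_rows: int = 40
    n_cols: int = 40
    n_years: int = 6
    zone_fractions: tuple[float, float, float] = (0.35, 0.35, 0.30)  # low, high, unstable
    spatial_correlation_length: float = 4.0  # pixels
    base_low: float = -0.8
    base_high: float = 0.8
    base_unstable: float = 0.0
    sensitivity_stable: float = 0.1
    sensitivity_unstable: float = 1.2
    weather_sd: float = 1.0
    noise_shape: float = -4.0
    noise_scale: float = 0.4
    start_year: int = 2010
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.zone_fractions
        if len(f) != 3 or any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("zone_fractions must be 3 non-negative values summing to 1")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.spatial_correlation_length < 1:
            raise ValueError("spatial_correlation_length must be >= 1")


@dataclass
class SyntheticField:
    """One generated field: raw and normalized stacks plus the planted truth."""

    raw: YieldStack
    normalized: YieldStack
    truth: np.ndarray  # class-coded grid: 1 low_stable, 2 high_stable, 3 unstable
    weather: np.ndarray  # per-year scalar effects
    spec: SyntheticFieldSpec = field(repr=False, default=None)


def _latent_zones(spec: SyntheticFieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Contiguous zone map hitting the requested fractions up to ties."""
    noise = rng.standard_normal((spec.n_rows, spec.n_cols))
    smooth = ndimage.gaussian_filter(noise, sigma=spec.spatial_correlation_length)
    f_low, f_high, _ = spec.zone_fractions
    # low zone = lowest f_low of the surface; high zone = top f_high;
    # the middle band is the weather-sensitive unstable zone.
    q_low, q_high = np.quantile(smooth, [f_low, 1.0 - f_high])
    zones = np.full(smooth.shape, CLASS_UNSTABLE, dtype=np.uint8)
    zones[smooth <= q_low] = CLASS_LOW_STABLE
    zones[smooth > q_high] = CLASS_HIGH_STABLE
    return zones


def generate_field(
    spec: SyntheticFieldSpec, field_id: str = "synth-0", crops: tuple[Crop, ...] | None = None
) -> SyntheticField:
    """Generate one field's multi-year stack with known zone truth.

    Year *t*'s latent map is ``base(zone) + sensitivity(zone) * w_t + noise``
    with ``w_t ~ N(0, weather_sd^2)`` and skew-normal pixel noise centered to
    mean zero.  The latent values are mapped onto crop-typical raw Mg/ha
    scales; normalized maps are the per-map z-scores of the raw maps.
    """
    rng = np.random.default_rng(spec.seed)
    zones = _latent_zones(spec, rng)
    base = np.where(
        zones == CLASS_LOW_STABLE,
        spec.base_low,
        np.where(zones == CLASS_HIGH_STABLE, spec.base_high, spec.base_unstable),
    )
    sens = np.where(zones == CLASS_UNSTABLE, spec.sensitivity_unstable, spec.sensitivity_stable)
    weather = rng.standard_normal(spec.n_years) * spec.weather_sd

    # center the skew-normal so noise is mean-zero at any shape
    delta = spec.noise_shape / np.hypot(1.0, spec.noise_shape)
    noise_mean = spec.noise_scale * delta * np.sqrt(2.0 / np.pi)

    transform = GridTransform(pixel_size=30.0)
    raw_maps, norm_maps = [], []
    for t in range(spec.n_years):
        crop = (
            crops[t % len(crops)]
            if crops
            else _CROP_ROTATION[t % len(_CROP_ROTATION)]
        )
        noise = (
            stats.skewnorm.rvs(
                spec.noise_shape,
                scale=spec.noise_scale,
                size=zones.shape,
                random_state=rng,
            )
            - noise_mean
        )
        latent = base + sens * weather[t] + noise
        level, scale = _CROP_SCALE[crop]
        raw = YieldMap(
            level + scale * latent,
            np.ones(zones.shape, dtype=bool),
            field_id=field_id,
            year=spec.start_year + t,
            crop=crop,
            transform=transform,
        )
        raw_maps.append(raw)
        norm_maps.append(normalize_map(raw))
    return SyntheticField(
        raw=YieldStack(raw_maps),
        normalized=build_stack(norm_maps),
        truth=zones,
        weather=weather,
        spec=spec,
    )


def generate_dataset(
    n_fields: int,
    template: SyntheticFieldSpec | None = None,
    seed: int = 0,
    year_range: tuple[int, int] = (2, 12),
    size_range: tuple[int, int] = (30, 60),
    n_farmers: int = 8,
    out_dir: str | Path | None = None,
) -> tuple[list[SyntheticField], dict]:
    """Generate a jittered multi-field dataset plus a manifest.

    Field sizes and year counts vary uniformly in the given ranges; each
    field gets a farmer id and a crop rotation.  With ``out_dir`` set, the
    raw maps are written as ASCII grids and the manifest as JSON next to
    them.  Reproducible given ``seed``.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    template = template or SyntheticFieldSpec()
    rng = np.random.default_rng(seed)
    fields: list[SyntheticField] = []
    manifest: dict = {"n_fields": n_fields, "seed": seed, "fields": []}
    for k in range(n_fields):
        n_years = int(rng.integers(year_range[0], year_range[1] + 1))
        n_rows = int(rng.integers(size_range[0], size_range[1] + 1))
        n_cols = int(rng.integers(size_range[0], size_range[1] + 1))
        spec = replace(
            template,
            n_rows=n_rows,
            n_cols=n_cols,
            n_years=n_years,
            weather_sd=float(template.weather_sd * rng.uniform(0.5, 1.5)),
            seed=int(rng.integers(2**31 - 1)),
        )
        field_id = f"synth-{k:03d}"
        fld = generate_field(spec, field_id=field_id)
        fields.append(fld)
        entry = {
            "field_id": field_id,
            "farmer_id": f"farmer-{k % n_farmers:02d}",
            "years": fld.raw.years,
            "crops": [m.crop.value for m in fld.raw.maps],
            "shape": [n_rows, n_cols],
            "weather_sd": spec.weather_sd,
            "rasters": [],
        }
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            for m in fld.raw.maps:
                name = f"{field_id}_{m.year}_{m.crop.value}.asc"
                write_yield_map(out_dir / name, m)
                entry["rasters"].append(name)
        manifest["fields"].append(entry)
    if out_dir is not None:
        (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return fields, manifest
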