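"""Seasonal pasture accessibility from snow cover, elevation and camps.

Transhumance restricts where each stock class can graze in each season:

* early summer (May-Jun): herds are still at winter/spring camps and snow
  blocks the high pastures - accessible wherever seasonal fractional snow
  cover (FSC) is below a threshold (default 35%), any area;
* high summer (Jul-Sep): sheep and goats stay below an elevation cap
  (default 4500 m a.s.l.); yak and cattle graze the high pastures with no
  cap but keep off the winter-use areas;
* winter (Oct-Apr): grazing only in areas that maintain a winter camp, and
  only where mean winter FSC stays below a (snow-tolerant) threshold,
  default 78% - herds rely entirely on grazing, with no stored fodder.

Thresholds use strict "below" comparisons: a pixel exactly at the threshold
is excluded.  Grazing-area polygons are exclusive management units; pixels
belong to the single polygon containing their center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .errors import ConfigError, DataError
from .rasters import RasterLayer

__all__ = [
    "AccessibilityRules",
    "GrazingArea",
    "SPECIES_GROUPS",
    "resample_fsc",
    "rasterize_areas",
    "accessible_mask",
    "seasonal_accessible_area",
    "all_season_masks",
]

SPECIES_GROUPS = ("small_stock", "large_stock", "all")


@dataclass(frozen=True)
class AccessibilityRules:
    """Thresholds of the seasonal grazing rules (all strict 'below')."""

    spring_fsc_max: float = 35.0  # % FSC, early-summer accessibility
    winter_fsc_max: float = 78.0  # % mean winter FSC
    small_stock_summer_elev_max: float = 4500.0  # m a.s.l.
    winter_requires_winter_camp: bool = True
    high_summer_excludes_winter_areas_for_large_stock: bool = True

    def __post_init__(self) -> None:
        for name in ("spring_fsc_max", "winter_fsc_max"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ConfigError(f"{name} must be within [0, 100], got {v}")


@dataclass
class GrazingArea:
    """One informal grazing-management unit."""

    area_id: str
    geometry: shapely.Geometry
    has_winter_camp: bool = False
    camps: list = None

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise DataError(f"area {self.area_id}: invalid polygon geometry")
        if not self.geometry.area > 0:
            raise DataError(f"area {self.area_id}: zero-area polygon")


def resample_fsc(fsc: RasterLayer, target: RasterLayer) -> RasterLayer:
    """Nearest-neighbour resampling of a coarse FSC raster onto a fine grid.

    Each target pixel takes the value of the source cell containing its
    center; values are carried over exactly (no interpolation), so the output
    value set is a subset of the input's.
    """
    if fsc.crs != target.crs:
        raise DataError(f"CRS mismatch: FSC {fsc.crs!r} vs target {target.crs!r}")
    xs, ys = target.pixel_centers()
    row, col = fsc.index_of(xs, ys)
    inside = (row >= 0) & (row < fsc.shape[0]) & (col >= 0) & (col < fsc.shape[1])
    if not inside.any():
        raise DataError("FSC raster does not overlap the target grid")
    out = np.full(target.shape, fsc.nodata, dtype=fsc.data.dtype)
    out[inside] = fsc.data[row[inside], col[inside]]
    return RasterLayer(
        data=out,
        x_origin=target.x_origin,
        y_origin=target.y_origin,
        pixel_size=target.pixel_size,
        crs=target.crs,
        nodata=fsc.nodata,
        units=fsc.units,
    )


def rasterize_areas(areas: list, template: RasterLayer) -> RasterLayer:
    """Paint grazing-area indices onto the template grid (pixel-center test).

    Returns an int32 raster holding the index of the containing area in
    ``areas``, -1 outside all areas.  Areas must not overlap.
    """
    for i, a in enumerate(areas):
        for b in areas[i + 1 :]:
            inter = a.geometry.intersection(b.geometry)
            if inter.area > 1e-6 * min(a.geometry.area, b.geometry.area):
                raise DataError(
                    f"grazing areas {a.area_id} and {b.area_id} overlap; "
                    "areas must partition the landscape"
                )
    xs, ys = template.pixel_centers()
    out = np.full(template.shape, -1, dtype=np.int32)
    for idx, area in enumerate(areas):
        hit = shapely.contains_xy(area.geometry, xs.ravel(), ys.ravel()).reshape(
            template.shape
        )
        out[hit] = idx
    return template.with_data(out, units="area index")


def accessible_mask(
    season: str,
    species_group: str,
    fsc: RasterLayer | None,
    dem: RasterLayer | None,
    areas: list,
    area_index: RasterLayer,
    rules: AccessibilityRules = AccessibilityRules(),
) -> RasterLayer:
    """Boolean accessibility raster for one season and stock class.

    ``fsc`` must be the seasonal FSC field relevant to ``season`` (spring
    composite for early summer, mean winter composite for winter); it is
    ignored in high summer, as the DEM is outside it.
    """
    if species_group not in SPECIES_GROUPS:
        raise ConfigError(f"unknown species group {species_group!r}")
    in_area = area_index.data >= 0
    idx = area_index.data

    if season == "early_summer":
        if fsc is None:
            raise ConfigError("early-summer mask needs an FSC raster")
        area_index.require_grid(fsc, "FSC raster")
        mask = in_area & (fsc.filled(np.inf) < rules.spring_fsc_max)
    elif season == "high_summer":
        winter_area = np.zeros_like(in_area)
        for i, a in enumerate(areas):
            if a.has_winter_camp:
                winter_area |= idx == i
        if species_group == "small_stock":
            if dem is None:
                raise ConfigError("high-summer small-stock mask needs a DEM")
            area_index.require_grid(dem, "DEM")
            mask = in_area & (dem.filled(np.inf) < rules.small_stock_summer_elev_max)
        elif species_group == "large_stock":
            mask = in_area.copy()
            if rules.high_summer_excludes_winter_areas_for_large_stock:
                mask &= ~winter_area
        else:  # "all": union of what any stock class can reach
            small = accessible_mask(
                season, "small_stock", fsc, dem, areas, area_index, rules
            ).data.astype(bool)
            large = accessible_mask(
                season, "large_stock", fsc, dem, areas, area_index, rules
            ).data.astype(bool)
            mask = small | large
    elif season == "winter":
        if fsc is None:
            raise ConfigError("winter mask needs a mean-winter FSC raster")
        area_index.require_grid(fsc, "FSC raster")
        mask = in_area & (fsc.filled(np.inf) < rules.winter_fsc_max)
        if rules.winter_requires_winter_camp:
            camp_area = np.zeros_like(mask)
            for i, a in enumerate(areas):
                if a.has_winter_camp:
                    camp_area |= idx == i
            mask &= camp_area
    else:
        raise ConfigError(f"unknown season {season!r}")

    return area_index.with_data(mask.astype(np.uint8), units="accessible")


def all_season_masks(
    fsc_spring: RasterLayer,
    fsc_winter: RasterLayer,
    dem: RasterLayer,
    areas: list,
    area_index: RasterLayer,
    rules: AccessibilityRules = AccessibilityRules(),
) -> dict:
    """Masks for every (season, species_group) the assessment uses."""
    return {
        ("early_summer", "all"): accessible_mask(
            "early_summer", "all", fsc_spring, dem, areas, area_index, rules
        ),
        ("high_summer", "small_stock"): accessible_mask(
            "high_summer", "small_stock", None, dem, areas, area_index, rules
        ),
        ("high_summer", "large_stock"): accessible_mask(
            "high_summer", "large_stock", None, dem, areas, area_index, rules
        ),
        ("winter", "all"): accessible_mask(
            "winter", "all", fsc_winter, dem, areas, area_index, rules
        ),
    }


def seasonal_accessible_area(
    mask: RasterLayer, areas: list, area_index: RasterLayer
) -> pd.DataFrame:
    """Accessible hectares per grazing area under one mask."""
    area_index.require_grid(mask, "mask")
    px_ha = mask.pixel_area_ha
    rows = []
    acc = mask.data.astype(bool)
    for i, area in enumerate(areas):
        n = int(np.sum(acc & (area_index.data == i)))
        rows.append({"area_id": area.area_id, "accessible_ha": n * px_ha})
    return pd.DataFrame(rows)
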