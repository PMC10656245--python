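"""Synthetic landscape, grazing system, field campaign and census generator.

Every stage of the assessment can be exercised without any downloaded data:
this module fabricates a high-mountain dryland scene with known ground
truth - a DEM spanning the 3000-6000 m relief, an elevation-structured
vegetation-community mosaic, per-community annual production calibrated to
the magnitudes observed in Pamir rangelands (riparian ~1.7 t DM/ha/yr down
to dwarf-shrub steppe ~0.46 t), Sentinel-2-like reflectance bands that carry
a recoverable biomass signal through the vegetation indices, fractional snow
cover increasing with altitude (winter > spring), grazing-area polygons with
winter-camp flags, stratified biomass plots, exclosure pairs encoding a
configured productivity ratio, and censuses inverted from target utilization
rates.

Everything is deterministic for a fixed seed.  The generated bands are a
statistical emulation (linear biomass-reflectance links plus Gaussian noise);
they reproduce the *structure* the analysis assumes, not Sentinel-2 physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import energy_demand as ed
from .accessibility import (
    AccessibilityRules,
    GrazingArea,
    all_season_masks,
    rasterize_areas,
    resample_fsc,
)
from .capacity import AssessmentInputs, aggregate_available_energy
from .errors import ConfigError, DataError
from .forage_supply import SoilLine, build_mec_map, default_community_params
from .rasters import RasterLayer

import shapely

__all__ = [
    "LandscapeConfig",
    "Landscape",
    "generate_landscape",
    "generate_grazing_system",
    "generate_field_campaign",
    "generate_census",
    "true_area_supply",
]

CLASS_CODES = {
    1: "riparian_grassland",
    2: "salix_riparian",
    3: "salt_grass",
    4: "dwarf_shrub_steppe",
    5: "alpine_grassland",
}
NONVEG_CODE = 0

# Annual production magnitudes (kg DM/ha) typical of the five communities,
# used as generator means; SDs give moderate within-community variability.
DEFAULT_PRODUCTION = {
    "riparian_grassland": (1729.0, 300.0),
    "salix_riparian": (1982.0, 330.0),
    "salt_grass": (641.0, 130.0),
    "dwarf_shrub_steppe": (461.0, 100.0),
    "alpine_grassland": (900.0, 180.0),
}

# Landscape share of each class, assigned by elevation rank (valley floor
# first); the remainder is non-vegetated rock/snow at the top.
DEFAULT_FRACTIONS = {
    "riparian_grassland": 0.08,
    "salix_riparian": 0.05,
    "salt_grass": 0.12,
    "dwarf_shrub_steppe": 0.35,
    "alpine_grassland": 0.25,
}

# Reflectance response of each band to the scaled biomass signal v:
# band = base + gain * v + noise, v = standing biomass / 2000 kg DM/ha.
BAND_MODEL = {
    "B3": (0.09, 0.02),
    "B4": (0.13, -0.06),
    "B5": (0.14, -0.02),
    "B6": (0.15, 0.04),
    "B7": (0.17, 0.07),
    "B8": (0.20, 0.16),
    "B8a": (0.20, 0.15),
    "B11": (0.26, -0.08),
    "B12": (0.23, -0.07),
}

# Field-campaign stratification: plots per community (dwarf-shrub steppe is
# the most extensive class and gets the densest sampling; the Salix shrub
# community is not clipped, matching the field protocol).
DEFAULT_PLOTS_PER_CLASS = {
    "dwarf_shrub_steppe": 50,
    "riparian_grassland": 30,
    "alpine_grassland": 30,
    "salt_grass": 15,
}


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic scene; defaults emulate the study region."""

    n_rows: int = 300
    n_cols: int = 300
    pixel_size: float = 10.0
    x_origin: float = 500_000.0
    y_origin: float = 4_100_000.0
    crs: str = "EPSG:32643"
    elev_min: float = 3000.0
    elev_max: float = 6000.0
    fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    production: dict = field(default_factory=lambda: dict(DEFAULT_PRODUCTION))
    true_productivity_ratio: float = 1.4
    band_noise_sd: float = 0.008
    soil_line: SoilLine = field(default_factory=lambda: SoilLine(alpha=1.2, beta=0.04))
    fsc_pixel_size: float = 500.0
    n_areas: int = 4
    n_winter_areas: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if not 0 < total <= 1 + 1e-9:
            raise ConfigError(
                f"community fractions must sum to at most 1, got {total:.3f}"
            )
        if any(sd < 0 for _, sd in self.production.values()):
            raise ConfigError("production SDs must be >= 0")


@dataclass
class Landscape:
    """Generated rasters plus the ground truth they were drawn from."""

    config: LandscapeConfig
    dem: RasterLayer
    communities: RasterLayer
    standing_biomass: RasterLayer  # true standing crop, kg DM/ha
    bands: dict  # B3..B12 reflectance arrays
    fsc_spring_coarse: RasterLayer
    fsc_winter_coarse: RasterLayer
    fsc_spring: RasterLayer  # resampled to the 10 m grid
    fsc_winter: RasterLayer
    true_production: RasterLayer  # kg DM/ha/yr
    true_mec: RasterLayer  # MJ/ha/yr
    class_codes: dict = field(default_factory=lambda: dict(CLASS_CODES))


def _smooth_noise(rng, shape, sigma):
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma)
    return smooth / (smooth.std() + 1e-12)


def _template(cfg: LandscapeConfig, data, units="") -> RasterLayer:
    return RasterLayer(
        data=data,
        x_origin=cfg.x_origin,
        y_origin=cfg.y_origin,
        pixel_size=cfg.pixel_size,
        crs=cfg.crs,
        units=units,
    )


def generate_landscape(config: LandscapeConfig, seed: int | None = None) -> Landscape:
    """Draw the full raster stack with ground truth; bit-reproducible per seed."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    shape = (config.n_rows, config.n_cols)

    # Elevation: south-to-north ramp with smooth relief noise
    ramp = np.linspace(1.0, 0.0, config.n_rows)[:, None] * np.ones((1, config.n_cols))
    relief = _smooth_noise(rng, shape, sigma=8) * 0.06
    elev_norm = np.clip(ramp + relief, 0, 1)
    dem_data = config.elev_min + (config.elev_max - config.elev_min) * elev_norm
    dem = _template(config, dem_data.astype(np.float32), units="m")

    # Communities by elevation rank: lowest pixels riparian, then Salix,
    # salt grass, dwarf-shrub, alpine; the highest remainder non-vegetated.
    order = np.argsort(dem_data, axis=None)
    cls = np.full(dem_data.size, NONVEG_CODE, dtype=np.int16)
    start = 0
    for code, cid in CLASS_CODES.items():
        n = int(round(config.fractions.get(cid, 0.0) * dem_data.size))
        cls[order[start : start + n]] = code
        start += n
    communities = _template(config, cls.reshape(shape), units="class")

    # True annual production and standing biomass
    production = np.zeros(shape, dtype=float)
    spatial = 1.0 + 0.12 * _smooth_noise(rng, shape, sigma=6)
    for code, cid in CLASS_CODES.items():
        mean, sd = config.production[cid]
        sel = communities.data == code
        draw = rng.normal(mean, sd, size=int(sel.sum()))
        production[sel] = np.maximum(draw, 0.05 * mean)
    production *= np.clip(spatial, 0.6, 1.4)
    production[communities.data == NONVEG_CODE] = 0.0
    standing = production / config.true_productivity_ratio

    # Reflectance bands carrying the biomass signal
    v = standing / 2000.0
    bands = {}
    for name, (base, gain) in BAND_MODEL.items():
        noise = rng.normal(0.0, config.band_noise_sd, size=shape)
        bands[name] = np.clip(base + gain * v + noise, 0.0, 1.0).astype(np.float32)

    # Fractional snow cover on a coarse grid, altitude-driven, winter > spring
    cpx = config.fsc_pixel_size
    n_crow = int(np.ceil(config.n_rows * config.pixel_size / cpx))
    n_ccol = int(np.ceil(config.n_cols * config.pixel_size / cpx))
    cxs = config.x_origin + (np.arange(n_ccol) + 0.5) * cpx
    cys = config.y_origin - (np.arange(n_crow) + 0.5) * cpx
    cx, cy = np.meshgrid(cxs, cys)
    row, col = dem.index_of(cx, cy)
    row = np.clip(row, 0, config.n_rows - 1)
    col = np.clip(col, 0, config.n_cols - 1)
    coarse_elev = dem_data[row, col]
    spring = np.clip((coarse_elev - 3600.0) / 12.0, 0.0, 100.0)
    spring = np.clip(spring + rng.normal(0, 3.0, size=spring.shape), 0.0, 100.0)
    winter = np.clip(spring + 35.0 + rng.normal(0, 3.0, size=spring.shape), 0.0, 100.0)

    def _coarse(dat):
        return RasterLayer(
            data=dat.astype(np.float32),
            x_origin=config.x_origin,
            y_origin=config.y_origin,
            pixel_size=cpx,
            crs=config.crs,
            units="% FSC",
        )

    fsc_spring_c, fsc_winter_c = _coarse(spring), _coarse(winter)
    template = _template(config, np.zeros(shape, dtype=np.float32))
    fsc_spring = resample_fsc(fsc_spring_c, template)
    fsc_winter = resample_fsc(fsc_winter_c, template)

    params = default_community_params(config.true_productivity_ratio)
    standing_layer = _template(config, standing.astype(np.float32), units="kg DM/ha")
    true_mec = build_mec_map(standing_layer, communities, params, CLASS_CODES)

    return Landscape(
        config=config,
        dem=dem,
        communities=communities,
        standing_biomass=standing_layer,
        bands=bands,
        fsc_spring_coarse=fsc_spring_c,
        fsc_winter_coarse=fsc_winter_c,
        fsc_spring=fsc_spring,
        fsc_winter=fsc_winter,
        true_production=_template(
            config, production.astype(np.float32), units="kg DM/ha/yr"
        ),
        true_mec=true_mec,
    )


def generate_grazing_system(config: LandscapeConfig, seed: int | None = None) -> list:
    """Non-overlapping grazing areas tiling the extent (west-east strips so
    every unit spans the full valley-to-ridge elevation range, as real
    transhumance units do); the first ``n_winter_areas`` keep winter camps."""
    if config.n_areas < 1:
        raise ConfigError("need at least one grazing area")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed + 1)
    width_m = config.n_cols * config.pixel_size
    height_m = config.n_rows * config.pixel_size
    # slightly uneven strip widths
    widths = rng.uniform(0.8, 1.2, size=config.n_areas)
    edges = np.concatenate([[0.0], np.cumsum(widths) / widths.sum()]) * width_m
    areas = []
    for i in range(config.n_areas):
        x0 = config.x_origin + edges[i]
        x1 = config.x_origin + edges[i + 1]
        poly = shapely.box(x0, config.y_origin - height_m, x1, config.y_origin)
        has_camp = i < config.n_winter_areas
        # winter camps sit on the valley floor (southern, low-elevation edge)
        camp = shapely.Point((x0 + x1) / 2, config.y_origin - height_m + 200.0)
        areas.append(
            GrazingArea(
                area_id=f"area_{i + 1}",
                geometry=poly,
                has_winter_camp=has_camp,
                camps=[camp] if has_camp else [],
            )
        )
    return areas


def generate_field_campaign(
    landscape: Landscape,
    n_per_class: dict | None = None,
    plot_noise_sd: float = 0.3,
    seed: int | None = None,
    n_fresh_dry: int = 67,
    n_exclosures: int = 8,
):
    """Stratified biomass plots, exclosure pairs and fresh/dry samples.

    Plot observations are the true pixel standing biomass (converted to
    kg DM/100 m2) plus Gaussian clipping/weighing noise.  Exclosure pairs
    encode the configured productivity ratio with 5% pair-level scatter.
    Returns ``(plots, exclosure_pairs, fresh_dry)`` DataFrames.
    """
    cfg = landscape.config
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed + 2)
    n_per_class = dict(DEFAULT_PLOTS_PER_CLASS) if n_per_class is None else n_per_class

    code_of = {cid: code for code, cid in landscape.class_codes.items()}
    rows_out = []
    plot_id = 0
    for cid, n in n_per_class.items():
        sel = np.flatnonzero(landscape.communities.data.ravel() == code_of[cid])
        if len(sel) < n:
            raise DataError(f"community {cid} has only {len(sel)} pixels, need {n}")
        picks = rng.choice(sel, size=n, replace=False)
        r, c = np.unravel_index(picks, landscape.communities.shape)
        xs = cfg.x_origin + (c + 0.5) * cfg.pixel_size
        ys = cfg.y_origin - (r + 0.5) * cfg.pixel_size
        true = landscape.standing_biomass.data[r, c] / 100.0  # kg DM/100 m2
        obs = np.maximum(true + rng.normal(0, plot_noise_sd, size=n), 0.0)
        for j in range(n):
            plot_id += 1
            rows_out.append(
                {
                    "plot_id": f"plot_{plot_id:03d}",
                    "x": xs[j],
                    "y": ys[j],
                    "year": 2020,
                    "community_id": cid,
                    "biomass_kg_dm_per_100m2": float(obs[j]),
                    "row": int(r[j]),
                    "col": int(c[j]),
                }
            )
    plots = pd.DataFrame(rows_out)

    # Exclosure pairs cycling through the sampled communities
    cids = list(n_per_class)
    pairs = []
    for i in range(n_exclosures):
        cid = cids[i % len(cids)]
        mean_standing = (
            cfg.production[cid][0] / cfg.true_productivity_ratio / 100.0
        )  # kg/100 m2
        outside = max(mean_standing * rng.normal(1.0, 0.15), 0.05)
        inside = outside * cfg.true_productivity_ratio * rng.normal(1.0, 0.05)
        pairs.append(
            {
                "pair_id": f"excl_{i + 1}",
                "community_id": cid,
                "inside_total_kg": float(inside),
                "outside_standing_kg": float(outside),
            }
        )
    exclosures = pd.DataFrame(pairs)

    fresh = rng.uniform(0.5, 20.0, size=n_fresh_dry)
    dry = 0.32 * fresh + 0.2 + rng.normal(0, 0.6, size=n_fresh_dry)
    fresh_dry = pd.DataFrame({"fresh_kg": fresh, "dry_kg": np.maximum(dry, 0.01)})

    return plots, exclosures, fresh_dry


def true_area_supply(
    landscape: Landscape,
    areas: list,
    rules: AccessibilityRules | None = None,
) -> pd.DataFrame:
    """Ground-truth accessible annual energy per area (MJ), from the true
    MEC raster and the seasonal accessibility rules."""
    rules = rules or AccessibilityRules()
    area_index = rasterize_areas(areas, landscape.true_mec)
    masks = all_season_masks(
        landscape.fsc_spring,
        landscape.fsc_winter,
        landscape.dem,
        areas,
        area_index,
        rules,
    )
    return aggregate_available_energy(landscape.true_mec, areas, area_index, masks)


def generate_census(
    config: LandscapeConfig,
    seed: int,
    target_utilization: dict,
    landscape: Landscape,
    areas: list,
    profiles: dict | None = None,
    calendar: ed.SeasonCalendar | None = None,
    year: int = 2020,
    demand_shares: dict | None = None,
    winter_ratio: float = 0.45,
    young_fraction: float = 0.3,
) -> pd.DataFrame:
    """Invert the demand model: herds whose annual MER approximates
    ``target_utilization[area_id] x true accessible supply``.

    Annual demand is split across species by ``demand_shares`` (default
    sheep 0.40 / goat 0.30 / yak 0.25 / cattle 0.05), across age classes by
    ``young_fraction``, and the winter herd is ``winter_ratio`` of the
    summer herd (cattle leave after high summer).  Counts are integers, so
    the achieved utilization differs from the target by the rounding of a
    few animals.
    """
    profiles = profiles or ed.default_species_profiles()
    calendar = calendar or ed.SeasonCalendar()
    demand_shares = demand_shares or {
        "sheep": 0.40,
        "goat": 0.30,
        "yak": 0.25,
        "cattle": 0.05,
    }
    if any(t < 0 for t in target_utilization.values()):
        raise ConfigError("target utilizations must be >= 0")

    supply = true_area_supply(landscape, areas).set_index("area_id")["supply_mj"]
    camp = {a.area_id: a.has_winter_camp for a in areas}

    def daily(sp, age, season):
        return ed.field_metabolic_rate(profiles[sp].mass(age, season))

    records = []
    for area_id, target in target_utilization.items():
        if area_id not in supply.index:
            raise DataError(f"unknown area {area_id!r} in utilization targets")
        target_mj = target * float(supply[area_id])
        wr = winter_ratio if camp.get(area_id, False) else 0.0
        for sp, share in demand_shares.items():
            prof = profiles[sp]
            seasons = [s for s in calendar.seasons if s in prof.seasons]
            has_young = any(age == "young" for age, _ in prof.body_mass_g)
            yf = young_fraction if has_young else 0.0

            # energy of one summer-counted animal over the year, blending
            # age classes and the winter herd reduction
            def unit(age):
                e = 0.0
                for season in seasons:
                    w = wr if season == "winter" else 1.0
                    e += w * daily(sp, age, season) * calendar.days(season)
                return e

            blended = (1 - yf) * unit("adult") + (yf * unit("young") if yf else 0.0)
            n_total = int(np.floor(target_mj * share / blended + 0.5)) if blended else 0
            n_adult = int(np.floor((1 - yf) * n_total + 0.5))
            n_young = n_total - n_adult
            for age, n in (("adult", n_adult), ("young", n_young)):
                if n <= 0:
                    continue
                records.append(
                    {
                        "year": year,
                        "season": "summer",
                        "area_id": area_id,
                        "species": sp,
                        "age_class": age,
                        "count": n,
                        "imputed": False,
                    }
                )
                if "winter" in seasons and wr > 0:
                    n_w = int(np.floor(n * wr + 0.5))
                    if n_w > 0:
                        records.append(
                            {
                                "year": year,
                                "season": "winter",
                                "area_id": area_id,
                                "species": sp,
                                "age_class": age,
                                "count": n_w,
                                "imputed": False,
                            }
                        )
    return pd.DataFrame(
        records,
        columns=["year", "season", "area_id", "species", "age_class", "count", "imputed"],
    )
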