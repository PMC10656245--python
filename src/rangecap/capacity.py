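"""Utilization intensity, grazing potential and carrying capacity.

The assessment closes the energy balance per grazing area and year:

* supply = sum of annual metabolizable energy content (MEC, MJ/ha/yr) over
  the pixels accessible in at least one season (each pixel's annual
  production counts once, however many seasons it can be reached);
* demand = seasonal metabolizable energy requirements (MER) of the censused
  herds (plus, optionally, wild herbivores) summed over the year;
* utilization intensity = 100 x demand / supply (%);
* grazing potential = MEC per ha / annual MER per animal (animals/ha at
  100% utilization); carrying capacity = potential x the sustainable
  utilization fraction (default 0.40).

Utilization strictly above the sustainability threshold is classed
``unsustainable``; above 100% ``over_potential``; a rate exactly at the
threshold still counts as sustainable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import energy_demand as ed
from .accessibility import AccessibilityRules, all_season_masks, rasterize_areas
from .errors import ConfigError, DataError
from .forage_supply import build_mec_map
from .rasters import RasterLayer

__all__ = [
    "ScenarioConfig",
    "SCENARIOS",
    "scenario_config",
    "AssessmentInputs",
    "ScenarioResult",
    "aggregate_available_energy",
    "utilization_rate",
    "grazing_potential",
    "carrying_capacity",
    "classify_sustainability",
    "run_scenario",
]

SCENARIOS = ("basic", "mer_plus30", "conservative_biomass", "wildlife", "no_winter")


@dataclass(frozen=True)
class ScenarioConfig:
    """One assessment scenario.

    ``biomass_adjustment`` is subtracted from the standing-biomass raster
    (kg DM/ha) before MEC assembly; the conservative scenario sets it to
    half the biomass model's mean absolute error.
    """

    scenario_id: str = "basic"
    mer_factor: float = 1.0
    mer_exempt_species: tuple = ("yak",)
    biomass_adjustment: float = 0.0
    include_wildlife: bool = False
    include_winter_grazing: bool = True
    sustainable_utilization: float = 0.40

    def __post_init__(self) -> None:
        if not 0 < self.sustainable_utilization < 1:
            raise ConfigError("sustainable_utilization must be in (0, 1)")
        if not self.mer_factor > 0:
            raise ConfigError("mer_factor must be > 0")


def scenario_config(name: str, mean_mae_kg_ha: float = 0.0, **overrides) -> ScenarioConfig:
    """Preset scenario configurations by name.

    ``mean_mae_kg_ha`` is the biomass model's mean MAE (kg DM/ha) across the
    validation campaigns; the conservative scenario discounts standing
    biomass by half of it.
    """
    presets = {
        "basic": {},
        "mer_plus30": {"mer_factor": 1.3},
        "conservative_biomass": {"biomass_adjustment": 0.5 * mean_mae_kg_ha},
        "wildlife": {"include_wildlife": True},
        "no_winter": {"include_winter_grazing": False},
    }
    if name not in presets:
        raise ConfigError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    kwargs = {"scenario_id": name, **presets[name], **overrides}
    return ScenarioConfig(**kwargs)


# ---------------------------------------------------------------------------
# Elementary quantities
# ---------------------------------------------------------------------------


def utilization_rate(demand_mj: float, supply_mj: float) -> float:
    """Percentage of available forage energy consumed; inf when demand meets
    zero supply."""
    if demand_mj < 0 or supply_mj < 0:
        raise DataError("demand and supply must be non-negative")
    if supply_mj == 0:
        return 0.0 if demand_mj == 0 else float("inf")
    return 100.0 * demand_mj / supply_mj


def grazing_potential(mec_per_ha: float, annual_mer: float) -> float:
    """Animals one hectare can feed at 100% utilization (animals/ha/yr)."""
    if not annual_mer > 0:
        raise DataError("annual MER must be > 0")
    return mec_per_ha / annual_mer


def carrying_capacity(potential: float, sustainable_utilization: float = 0.40) -> float:
    """Sustainable stocking rate: grazing potential times the sustainable
    utilization fraction."""
    if potential < 0:
        raise DataError("grazing potential must be >= 0")
    return potential * sustainable_utilization


def classify_sustainability(utilization_pct: float, threshold: float = 0.40) -> str:
    """Class of a utilization rate: strict '>' at both boundaries."""
    if utilization_pct < 0:
        raise DataError("utilization must be >= 0")
    if utilization_pct > 100.0:
        return "over_potential"
    if utilization_pct > 100.0 * threshold:
        return "unsustainable"
    return "sustainable"


# ---------------------------------------------------------------------------
# Supply aggregation
# ---------------------------------------------------------------------------


def aggregate_available_energy(
    mec: RasterLayer,
    areas: list,
    area_index: RasterLayer,
    masks: dict,
) -> pd.DataFrame:
    """Annual accessible energy supply (MJ) per grazing area.

    A pixel contributes its annual MEC once if it is accessible under any of
    the provided seasonal masks.  Returns columns ``area_id``, ``supply_mj``,
    ``accessible_ha``.
    """
    mec.require_grid(area_index, "area-index raster")
    union = np.zeros(mec.shape, dtype=bool)
    for m in masks.values():
        mec.require_grid(m, "mask")
        union |= m.data.astype(bool)
    vals = mec.filled(np.nan)
    px_ha = mec.pixel_area_ha
    rows = []
    for i, area in enumerate(areas):
        sel = union & (area_index.data == i) & np.isfinite(vals)
        supply = float(vals[sel].sum() * px_ha)
        if not sel.any():
            rows.append({"area_id": area.area_id, "supply_mj": 0.0, "accessible_ha": 0.0})
            continue
        rows.append(
            {
                "area_id": area.area_id,
                "supply_mj": supply,
                "accessible_ha": float(sel.sum() * px_ha),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenario orchestration
# ---------------------------------------------------------------------------


@dataclass
class AssessmentInputs:
    """Everything one scenario run needs, already co-registered."""

    standing_biomass: RasterLayer  # kg DM/ha (July standing crop)
    communities: RasterLayer  # integer class codes
    class_codes: dict  # code -> community_id (vegetated classes only)
    community_params: dict  # community_id -> CommunityParams
    fsc_spring: RasterLayer  # % FSC, May-Jun composite
    fsc_winter: RasterLayer  # % FSC, Oct-Apr mean
    dem: RasterLayer  # m a.s.l.
    areas: list  # GrazingArea
    census: pd.DataFrame
    profiles: dict = field(default_factory=ed.default_species_profiles)
    wildlife_profiles: dict = field(default_factory=ed.default_wildlife_profiles)
    calendar: ed.SeasonCalendar = field(default_factory=ed.SeasonCalendar)
    rules: AccessibilityRules = field(default_factory=AccessibilityRules)
    allometry: ed.AllometricParams = field(default_factory=ed.AllometricParams)
    area_index: RasterLayer | None = None

    def __post_init__(self) -> None:
        for name in ("communities", "fsc_spring", "fsc_winter", "dem"):
            self.standing_biomass.require_grid(getattr(self, name), name)
        if self.area_index is None:
            self.area_index = rasterize_areas(self.areas, self.standing_biomass)

    def vegetated_mask(self) -> np.ndarray:
        veg = np.zeros(self.communities.shape, dtype=bool)
        for code in self.class_codes:
            veg |= self.communities.data == code
        return veg & self.communities.mask_valid()


@dataclass
class ScenarioResult:
    """Per-area table, per-pixel utilization raster and region aggregates."""

    scenario: ScenarioConfig
    results: pd.DataFrame  # area_id, year, supply, demand, utilization, class
    utilization: RasterLayer  # mean-over-years % rate on assessed pixels
    region: dict  # aggregate summary


def _yearly_demand(demand: pd.DataFrame) -> pd.DataFrame:
    grouped = (
        demand.groupby(["year", "area_id", "herbivore_group"])["energy_mj"].sum().unstack(
            fill_value=0.0
        )
    )
    grouped["demand_livestock_mj"] = grouped.get("livestock", 0.0)
    wild_cols = [c for c in ("marmot", "wild_ungulate") if c in grouped.columns]
    grouped["demand_wildlife_mj"] = grouped[wild_cols].sum(axis=1) if wild_cols else 0.0
    return grouped[["demand_livestock_mj", "demand_wildlife_mj"]].reset_index()


def run_scenario(inputs: AssessmentInputs, config: ScenarioConfig) -> ScenarioResult:
    """Run one scenario end to end.

    Orchestrates MEC assembly (with the scenario's biomass discount),
    accessibility masking (optionally without winter grazing), seasonal
    demand (with the MER factor, exemptions and optional wildlife) and the
    area-level energy balance.
    """
    try:
        mec = build_mec_map(
            inputs.standing_biomass,
            inputs.communities,
            inputs.community_params,
            inputs.class_codes,
            biomass_adjustment=config.biomass_adjustment,
        )
    except (ConfigError, DataError) as exc:
        raise type(exc)(f"supply stage: {exc}") from exc

    masks = all_season_masks(
        inputs.fsc_spring,
        inputs.fsc_winter,
        inputs.dem,
        inputs.areas,
        inputs.area_index,
        inputs.rules,
    )
    if not config.include_winter_grazing:
        masks = {k: v for k, v in masks.items() if k[0] != "winter"}

    supply = aggregate_available_energy(mec, inputs.areas, inputs.area_index, masks)
    for area_id in supply.loc[supply["supply_mj"] == 0.0, "area_id"]:
        warnings.warn(f"area {area_id} has no accessible energy supply")

    try:
        demand = ed.seasonal_area_demand(
            inputs.census, inputs.profiles, inputs.calendar, inputs.allometry
        )
    except (ConfigError, DataError) as exc:
        raise type(exc)(f"demand stage: {exc}") from exc
    if config.mer_factor != 1.0:
        demand = ed.apply_mer_scenario(demand, config.mer_factor, config.mer_exempt_species)

    years = sorted(demand["year"].unique()) if not demand.empty else []
    if config.include_wildlife and years:
        veg = inputs.vegetated_mask()
        px_km2 = inputs.standing_biomass.pixel_size**2 / 1e6
        veg_by_area = {
            a.area_id: float(np.sum(veg & (inputs.area_index.data == i)) * px_km2)
            for i, a in enumerate(inputs.areas)
        }
        total_veg = sum(veg_by_area.values())
        wild = pd.concat(
            [
                ed.wildlife_demand(
                    total_veg,
                    inputs.wildlife_profiles,
                    veg_by_area,
                    year=yr,
                    calendar=inputs.calendar,
                    params=inputs.allometry,
                )
                for yr in years
            ],
            ignore_index=True,
        )
        if not wild.empty:
            demand = pd.concat([demand, wild], ignore_index=True)

    if not config.include_winter_grazing and not demand.empty:
        demand = demand[demand["season"] != "winter"]

    if demand.empty:
        yearly = pd.DataFrame(
            columns=["year", "area_id", "demand_livestock_mj", "demand_wildlife_mj"]
        )
    else:
        yearly = _yearly_demand(demand)

    rows = []
    supply_by_area = supply.set_index("area_id")["supply_mj"]
    for _, rec in yearly.iterrows():
        if rec["area_id"] not in supply_by_area.index:
            raise DataError(f"assessment stage: census names unknown area {rec['area_id']!r}")
        s = float(supply_by_area[rec["area_id"]])
        d = float(rec["demand_livestock_mj"] + rec["demand_wildlife_mj"])
        u = utilization_rate(d, s)
        rows.append(
            {
                "area_id": rec["area_id"],
                "year": rec["year"],
                "scenario": config.scenario_id,
                "supply_mj": s,
                "demand_livestock_mj": float(rec["demand_livestock_mj"]),
                "demand_wildlife_mj": float(rec["demand_wildlife_mj"]),
                "utilization_pct": u,
                "class": classify_sustainability(u, config.sustainable_utilization)
                if np.isfinite(u)
                else "over_potential",
            }
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "area_id",
            "year",
            "scenario",
            "supply_mj",
            "demand_livestock_mj",
            "demand_wildlife_mj",
            "utilization_pct",
            "class",
        ],
    )

    # --- utilization raster + region aggregates over assessed pixels ------
    union = np.zeros(mec.shape, dtype=bool)
    for m in masks.values():
        union |= m.data.astype(bool)
    assessed = union & inputs.vegetated_mask()
    util_grid = np.full(mec.shape, np.nan, dtype=np.float32)
    mean_by_area = (
        results.replace([np.inf], np.nan)
        .groupby("area_id")["utilization_pct"]
        .mean()
        if not results.empty
        else pd.Series(dtype=float)
    )
    for i, area in enumerate(inputs.areas):
        if area.area_id in mean_by_area.index and np.isfinite(mean_by_area[area.area_id]):
            util_grid[assessed & (inputs.area_index.data == i)] = mean_by_area[area.area_id]
    util_raster = mec.with_data(util_grid, units="% utilization")

    painted = np.isfinite(util_grid)
    region = {
        "mean_utilization_pct_areas": float(mean_by_area.mean())
        if len(mean_by_area)
        else np.nan,
        "mean_utilization_pct_pixels": float(np.nanmean(util_grid))
        if painted.any()
        else np.nan,
        "pct_area_unsustainable": (
            100.0
            * float(
                np.sum(util_grid[painted] > 100.0 * config.sustainable_utilization)
            )
            / float(painted.sum())
            if painted.any()
            else np.nan
        ),
        "assessed_ha": float(assessed.sum() * mec.pixel_area_ha),
    }
    return ScenarioResult(config, results, util_raster, region)
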