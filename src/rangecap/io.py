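"""File formats, run configuration and provenance.

Tables are UTF-8 CSV with headers; rasters GeoTIFF (see :mod:`.rasters`);
grazing areas GeoJSON FeatureCollections with ``area_id`` and
``has_winter_camp`` properties.  A run is driven by one YAML file that names
every input and parameter block; validation reports *all* problems at once
so a bad config fails in a single round trip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import mapping, shape

from . import __version__
from .accessibility import AccessibilityRules, GrazingArea
from .capacity import SCENARIOS
from .energy_demand import AllometricParams, SeasonCalendar
from .errors import ConfigError, DataError
from .forage_supply import SoilLine
from .rasters import RasterLayer, read_raster, write_raster  # re-export

__all__ = [
    "read_raster",
    "write_raster",
    "read_table",
    "write_table",
    "read_areas",
    "write_areas",
    "RunConfig",
    "validate_run_config",
    "write_provenance",
]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, encoding="utf-8")


def write_areas(path, areas: list, crs: str = "") -> None:
    """Write grazing areas as a GeoJSON FeatureCollection."""
    features = []
    for a in areas:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(a.geometry),
                "properties": {
                    "area_id": a.area_id,
                    "has_winter_camp": bool(a.has_winter_camp),
                    "camps": [[p.x, p.y] for p in (a.camps or [])],
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if crs:
        doc["crs_note"] = crs
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_areas(path) -> list:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("type") != "FeatureCollection":
        raise DataError(f"{path}: not a GeoJSON FeatureCollection")
    areas = []
    for feat in doc["features"]:
        props = feat.get("properties", {})
        if "area_id" not in props:
            raise DataError(f"{path}: feature without area_id property")
        areas.append(
            GrazingArea(
                area_id=str(props["area_id"]),
                geometry=shape(feat["geometry"]),
                has_winter_camp=bool(props.get("has_winter_camp", False)),
                camps=[shapely.Point(xy) for xy in props.get("camps", [])],
            )
        )
    return areas


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_INPUT_KEYS = {
    "standing_biomass",
    "communities",
    "dem",
    "fsc_spring",
    "fsc_winter",
    "areas",
    "census",
    "plots",
    "exclosures",
    "fresh_dry",
    "bands",
}
_REQUIRED_INPUTS = {"communities", "dem", "fsc_spring", "fsc_winter", "areas", "census"}
_TOP_KEYS = {"seed", "output_dir", "log_level", "inputs", "parameters", "scenarios"}


@dataclass
class RunConfig:
    """Fully resolved, validated run description."""

    path: Path
    seed: int
    output_dir: Path
    log_level: str
    inputs: dict  # name -> resolved Path (bands -> dict band -> Path)
    scenarios: list
    allometry: AllometricParams
    calendar: SeasonCalendar
    rules: AccessibilityRules
    soil_line: SoilLine | None
    class_codes: dict
    forage_quality: dict
    consumable_fraction: dict
    productivity_ratio: float | None
    sustainable_utilization: float
    mean_mae_kg_ha: float
    raw: dict = field(repr=False, default_factory=dict)


_DEFAULT_CLASS_CODES = {
    1: "riparian_grassland",
    2: "salix_riparian",
    3: "salt_grass",
    4: "dwarf_shrub_steppe",
    5: "alpine_grassland",
}


def validate_run_config(path) -> RunConfig:
    """Parse and validate a YAML run config, resolving relative paths
    against the config file's directory; every problem is reported in one
    aggregated :class:`ConfigError`."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    errors: list[str] = []
    base = path.parent

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level key(s): {sorted(unknown)}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")
        seed = 0

    inputs_raw = raw.get("inputs", {}) or {}
    unknown_inputs = set(inputs_raw) - _INPUT_KEYS
    if unknown_inputs:
        errors.append(f"unknown input key(s): {sorted(unknown_inputs)}")
    missing_required = _REQUIRED_INPUTS - set(inputs_raw)
    if missing_required:
        errors.append(f"missing required input(s): {sorted(missing_required)}")
    if "standing_biomass" not in inputs_raw and "bands" not in inputs_raw:
        errors.append("need either a standing_biomass raster or bands + plots")
    if "bands" in inputs_raw and "plots" not in inputs_raw:
        errors.append("band inputs require a plots table to fit the biomass model")

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    inputs: dict = {}
    for key, value in inputs_raw.items():
        if key == "bands":
            if not isinstance(value, dict):
                errors.append("inputs.bands must map band names to paths")
                continue
            inputs["bands"] = {}
            for band, bpath in value.items():
                rp = resolve(bpath)
                if not rp.exists():
                    errors.append(f"inputs.bands.{band}: file not found: {rp}")
                inputs["bands"][band] = rp
            continue
        rp = resolve(value)
        if not rp.exists():
            errors.append(f"inputs.{key}: file not found: {rp}")
        inputs[key] = rp

    scenarios = raw.get("scenarios", ["basic"])
    if isinstance(scenarios, str):
        scenarios = [scenarios]
    for s in scenarios:
        if s not in SCENARIOS:
            errors.append(f"unknown scenario {s!r}; expected one of {SCENARIOS}")

    params = raw.get("parameters", {}) or {}

    def build(name, fn):
        try:
            return fn()
        except (ConfigError, TypeError, KeyError, ValueError) as exc:
            errors.append(f"parameters.{name}: {exc}")
            return None

    allometry = build("allometric", lambda: AllometricParams(**params.get("allometric", {})))
    calendar = build(
        "calendar",
        lambda: SeasonCalendar(day_counts=dict(params["calendar"]))
        if "calendar" in params
        else SeasonCalendar(),
    )
    rules = build("rules", lambda: AccessibilityRules(**params.get("rules", {})))
    soil_line = None
    if "soil_line" in params:
        soil_line = build("soil_line", lambda: SoilLine(**params["soil_line"]))
    elif "bands" in inputs_raw:
        errors.append("parameters.soil_line (alpha, beta) is required with band inputs")

    class_codes = {
        int(k): str(v) for k, v in params.get("class_codes", _DEFAULT_CLASS_CODES).items()
    }
    sustainable = params.get("sustainable_utilization", 0.40)
    if not 0 < sustainable < 1:
        errors.append(f"sustainable_utilization must be in (0, 1), got {sustainable}")

    if errors:
        raise ConfigError(
            f"invalid run config {path}:\n  - " + "\n  - ".join(str(e) for e in errors)
        )

    return RunConfig(
        path=path,
        seed=seed,
        output_dir=resolve(raw.get("output_dir", "out")),
        log_level=str(raw.get("log_level", "INFO")),
        inputs=inputs,
        scenarios=list(scenarios),
        allometry=allometry,
        calendar=calendar,
        rules=rules,
        soil_line=soil_line,
        class_codes=class_codes,
        forage_quality=dict(params.get("forage_quality", {})),
        consumable_fraction=dict(params.get("consumable_fraction", {})),
        productivity_ratio=params.get("productivity_ratio"),
        sustainable_utilization=float(sustainable),
        mean_mae_kg_ha=float(params.get("mean_mae_kg_ha", 0.0)),
        raw=raw,
    )


def write_provenance(out_dir, config_path, seed: int) -> Path:
    """Emit a machine-readable record sufficient to rerun bit-compatibly."""
    import sklearn

    config_path = Path(config_path)
    record = {
        "config": str(config_path),
        "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        "seed": int(seed),
        "versions": {
            "rangecap": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    out = Path(out_dir) / "provenance.json"
    out.write_text(json.dumps(record, indent=2), encoding="utf-8")
    return out
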