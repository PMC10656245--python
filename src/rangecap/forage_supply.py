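"""Metabolizable energy content (MEC) of the vegetation.

The supply side of the assessment chains four estimates:

1. standing biomass from multispectral reflectance: eight vegetation indices
   (soil-adjusted red/NIR, red-edge and SWIR families) feed a random-forest
   regressor trained on clipped field plots, error-characterised by repeated
   spatial (coordinate-blocked) cross-validation;
2. a fresh-to-dry linear conversion for plots weighed fresh in the field;
3. a productivity ratio (annual production / standing biomass) from paired
   exclosure / grazed clippings, turning a July standing-biomass map into
   annual production;
4. per-community forage parameters: metabolizable energy per kg dry matter
   and the fraction of biomass herbivores can physically consume (0.5 in
   woody dwarf-shrub communities, 0.8 elsewhere).

Units: field plots in kg DM/100 m2, rasters in kg DM/ha (x100 at the
plot-raster boundary), MEC in MJ/ha/year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestRegressor

from .errors import ConfigError, DataError
from .rasters import RasterLayer

__all__ = [
    "SoilLine",
    "CommunityParams",
    "ModelMetrics",
    "VEGETATION_COMMUNITIES",
    "default_community_params",
    "INDEX_NAMES",
    "compute_vegetation_indices",
    "fit_fresh_dry_model",
    "BiomassModel",
    "fit_biomass_model",
    "regression_metrics",
    "spatial_cross_validate",
    "productivity_ratio",
    "build_mec_map",
    "KG_PER_100M2_TO_KG_PER_HA",
]

KG_PER_100M2_TO_KG_PER_HA = 100.0  # 1 ha = 100 x (100 m2)

VEGETATION_COMMUNITIES = (
    "riparian_grassland",
    "salix_riparian",
    "salt_grass",
    "dwarf_shrub_steppe",
    "alpine_grassland",
)


@dataclass(frozen=True)
class SoilLine:
    """Bare-soil line in red/NIR reflectance space (slope alpha, intercept
    beta); required by the soil-adjusted indices, site-specific, no default."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ConfigError("soil line slope alpha must be > 0")


@dataclass
class CommunityParams:
    """Forage parameters of one vegetation community.

    forage_quality: metabolizable energy of the dry matter, MJ/kg DM.
    consumable_fraction: share of biomass ingestible by herbivores.
    productivity_ratio: annual production / July standing biomass.
    """

    community_id: str
    forage_quality: float
    consumable_fraction: float
    productivity_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not self.forage_quality > 0:
            raise ConfigError(f"{self.community_id}: forage quality must be > 0")
        if not 0 < self.consumable_fraction <= 1:
            raise ConfigError(f"{self.community_id}: consumable fraction must be in (0, 1]")
        if not self.productivity_ratio > 0:
            raise ConfigError(f"{self.community_id}: productivity ratio must be > 0")


def default_community_params(productivity_ratio: float = 1.0) -> dict:
    """Default forage quality (MJ/kg DM) and consumable fractions for the
    five Pamir vegetation communities; riparian and Salix communities are
    richest, dwarf-shrub steppe poorest and half woody."""
    quality = {
        "riparian_grassland": 9.4,
        "salix_riparian": 9.4,
        "salt_grass": 9.1,
        "dwarf_shrub_steppe": 6.3,
        "alpine_grassland": 9.1,
    }
    return {
        cid: CommunityParams(
            cid,
            forage_quality=quality[cid],
            consumable_fraction=0.5 if cid == "dwarf_shrub_steppe" else 0.8,
            productivity_ratio=productivity_ratio,
        )
        for cid in VEGETATION_COMMUNITIES
    }


# ---------------------------------------------------------------------------
# Vegetation indices
# ---------------------------------------------------------------------------

INDEX_NAMES = ("WDVI", "WDVI_SA", "RatioB8aB3", "NDRE1", "NDRE2", "MTCI", "SACRI", "MSACRI")

_REQUIRED_BANDS = {
    "WDVI": ("B8", "B4"),
    "WDVI_SA": ("B8", "B4", "B3"),
    "RatioB8aB3": ("B8a", "B3"),
    "NDRE1": ("B8", "B7"),
    "NDRE2": ("B8", "B8a"),
    "MTCI": ("B6", "B5", "B4"),
    "SACRI": ("B8", "B11"),
    "MSACRI": ("B11", "B12"),
}


def _safe_divide(num, den):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(np.isfinite(out), out, np.nan)


def compute_vegetation_indices(bands: dict, soil: SoilLine) -> dict:
    """Eight vegetation indices from Sentinel-2-style reflectance bands.

    ``bands`` maps band names (B3..B12) to equally shaped arrays of surface
    reflectance in [0, 1].  Division-by-zero pixels become NaN.
    """
    for index, needed in _REQUIRED_BANDS.items():
        missing = [b for b in needed if b not in bands]
        if missing:
            raise DataError(f"index {index} needs missing band(s) {missing}")
    shapes = {np.shape(v) for v in bands.values()}
    if len(shapes) > 1:
        raise DataError(f"bands are not co-registered: shapes {sorted(shapes)}")

    b = {k: np.asarray(v, dtype=float) for k, v in bands.items()}
    a, beta = soil.alpha, soil.beta

    wdvi = b["B8"] - a * b["B4"]
    out = {
        "WDVI": wdvi,
        "WDVI_SA": wdvi - 0.45 * _safe_divide(b["B4"] - b["B3"], b["B4"] + b["B3"]),
        "RatioB8aB3": _safe_divide(b["B8a"], b["B3"]),
        "NDRE1": _safe_divide(b["B8"] - b["B7"], b["B8"] + b["B7"]),
        "NDRE2": _safe_divide(b["B8"] - b["B8a"], b["B8"] + b["B8a"]),
        "MTCI": _safe_divide(b["B6"] - b["B5"], b["B5"] + b["B4"]),
        "SACRI": _safe_divide(
            a * (b["B8"] - b["B11"] - beta), a * b["B8"] + b["B11"] - a * beta
        ),
        "MSACRI": 5.0
        * _safe_divide(
            a * (b["B11"] - a * b["B12"] - beta), a * b["B11"] + b["B12"] + a * beta
        ),
    }
    return out


# ---------------------------------------------------------------------------
# Fresh-dry conversion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FreshDryModel:
    slope: float
    intercept: float
    r2: float
    n: int

    def convert(self, fresh):
        return self.slope * np.asarray(fresh, dtype=float) + self.intercept


def fit_fresh_dry_model(fresh, dry) -> FreshDryModel:
    """Ordinary least squares ``dry ~ fresh`` for plots weighed fresh only."""
    fresh = np.asarray(fresh, dtype=float)
    dry = np.asarray(dry, dtype=float)
    if fresh.size != dry.size:
        raise DataError("fresh and dry sample vectors differ in length")
    if fresh.size < 3:
        raise DataError("fresh-dry model needs at least 3 sample pairs")
    if np.allclose(fresh, fresh[0]):
        raise DataError("fresh masses are constant; slope is unidentifiable")
    res = stats.linregress(fresh, dry)
    return FreshDryModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=int(fresh.size),
    )


# ---------------------------------------------------------------------------
# Biomass regression
# ---------------------------------------------------------------------------


class BiomassModel:
    """Random-forest standing-biomass regressor over the 8 indices.

    Thin wrapper that fixes the feature order and clamps predictions at
    zero (biomass cannot be negative).
    """

    def __init__(self, n_trees: int = 500, seed: int | None = None):
        self.n_trees = n_trees
        self.seed = seed
        self._rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
        self.features = list(INDEX_NAMES)

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "BiomassModel":
        X = pd.DataFrame(X)[self.features]
        if X.isna().any().any():
            bad = X.index[X.isna().any(axis=1)].tolist()
            raise DataError(f"NaN index values at plots {bad[:10]}")
        self._rf.fit(X.to_numpy(), np.asarray(y, dtype=float))
        return self

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)[self.features]
        pred = self._rf.predict(X.to_numpy())
        return np.maximum(pred, 0.0)

    def predict_raster(self, indices: dict, template: RasterLayer) -> RasterLayer:
        """Predict a standing-biomass raster (kg DM/ha) from index grids."""
        stack = np.stack([indices[f] for f in self.features], axis=-1)
        flat = stack.reshape(-1, len(self.features))
        valid = np.isfinite(flat).all(axis=1)
        out = np.full(flat.shape[0], np.nan, dtype=float)
        if valid.any():
            out[valid] = np.maximum(self._rf.predict(flat[valid]), 0.0)
        grid = out.reshape(template.shape) * KG_PER_100M2_TO_KG_PER_HA
        return template.with_data(grid.astype(np.float32), units="kg DM/ha")


def fit_biomass_model(
    plots: pd.DataFrame,
    index_values: pd.DataFrame,
    n_trees: int = 500,
    seed: int | None = None,
    min_plots: int = 20,
) -> BiomassModel:
    """Fit the standing-biomass model on field plots.

    ``plots`` must carry ``biomass_kg_dm_per_100m2``; ``index_values`` the
    8 index columns aligned row-wise with ``plots``.
    """
    if len(plots) < min_plots:
        raise DataError(f"need at least {min_plots} plots, got {len(plots)}")
    y = plots["biomass_kg_dm_per_100m2"].to_numpy(dtype=float)
    return BiomassModel(n_trees=n_trees, seed=seed).fit(index_values, y)


# ---------------------------------------------------------------------------
# Validation metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelMetrics:
    """Error measures of a biomass model; absolute metrics share the unit of
    the observations (kg DM/100 m2), relative ones are % of the observed
    mean."""

    r2: float
    rmse: float
    rmse_rel: float
    mae: float
    mae_rel: float
    bias: float
    bias_rel: float
    obs_mean: float
    obs_sd: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def regression_metrics(obs, pred) -> ModelMetrics:
    """R2, RMSE, MAE and BIAS with relative forms (% of observed mean)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.size != pred.size:
        raise DataError("obs and pred differ in length")
    if obs.size < 2:
        raise DataError("need at least 2 observations")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    bias = float(np.mean(err))
    mean = float(np.mean(obs))
    sst = float(np.sum((obs - mean) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else np.nan
    if mean == 0:
        warnings.warn("observed mean is 0; relative metrics undefined (NaN)")
        rel = (np.nan, np.nan, np.nan)
    else:
        rel = tuple(100.0 * m / mean for m in (rmse, mae, bias))
    return ModelMetrics(
        r2=r2,
        rmse=rmse,
        rmse_rel=rel[0],
        mae=mae,
        mae_rel=rel[1],
        bias=bias,
        bias_rel=rel[2],
        obs_mean=mean,
        obs_sd=float(np.std(obs, ddof=1)),
    )


def spatial_cross_validate(
    plots: pd.DataFrame,
    index_values: pd.DataFrame,
    k: int = 10,
    repeats: int = 100,
    n_trees: int = 500,
    seed: int = 0,
) -> ModelMetrics:
    """Repeated k-fold spatial cross-validation of the biomass model.

    Folds are spatial blocks: per repeat, plot coordinates (columns ``x``,
    ``y``) are clustered into ``k`` groups with k-means (repeat-indexed
    seeds), each cluster held out in turn.  Held-out predictions are pooled
    into per-repeat metrics, then averaged over repeats.
    """
    n = len(plots)
    if k > n:
        raise DataError(f"k={k} folds exceed n={n} plots")
    if not {"x", "y"}.issubset(plots.columns):
        raise DataError("plots need coordinate columns 'x' and 'y'")
    coords = plots[["x", "y"]].to_numpy(dtype=float)
    y = plots["biomass_kg_dm_per_100m2"].to_numpy(dtype=float)
    X = pd.DataFrame(index_values)[list(INDEX_NAMES)].reset_index(drop=True)

    per_repeat = []
    for rep in range(repeats):
        rep_seed = (seed + 1) * 10_000 + rep
        km = KMeans(n_clusters=k, n_init=5, random_state=rep_seed % (2**31))
        fold = km.fit_predict(coords)
        pooled_pred = np.empty(n)
        for g in np.unique(fold):
            test = fold == g
            model = BiomassModel(n_trees=n_trees, seed=rep_seed % (2**31))
            model.fit(X.loc[~test], y[~test])
            pooled_pred[test] = model.predict(X.loc[test])
        per_repeat.append(regression_metrics(y, pooled_pred).as_dict())
    mean_metrics = pd.DataFrame(per_repeat).mean()
    return ModelMetrics(**mean_metrics.to_dict())


# ---------------------------------------------------------------------------
# Productivity and MEC assembly
# ---------------------------------------------------------------------------


def productivity_ratio(pairs: pd.DataFrame, pooling: str = "global"):
    """Annual-production / standing-biomass ratio from exclosure pairs.

    ``pairs`` columns: ``community_id``, ``inside_total_kg`` (season-end clip
    inside the exclosure), ``outside_standing_kg`` (identical grazed area).
    ``pooling='global'`` returns one float over all valid pairs;
    ``'community'`` a dict per community.  Pairs with zero grazed standing
    biomass are dropped with a warning; a single surviving pair is accepted
    but flagged low-confidence.
    """
    valid = pairs[pairs["outside_standing_kg"] > 0].copy()
    dropped = len(pairs) - len(valid)
    if dropped:
        warnings.warn(f"dropped {dropped} exclosure pair(s) with zero grazed biomass")
    if valid.empty:
        raise DataError("no valid exclosure pairs for productivity ratio")
    valid["ratio"] = valid["inside_total_kg"] / valid["outside_standing_kg"]
    if len(valid) == 1:
        warnings.warn("productivity ratio rests on a single exclosure pair (low confidence)")
    if pooling == "global":
        return float(valid["ratio"].mean())
    if pooling == "community":
        return valid.groupby("community_id")["ratio"].mean().to_dict()
    raise ConfigError(f"unknown pooling {pooling!r}; use 'global' or 'community'")


def build_mec_map(
    standing_biomass: RasterLayer,
    communities: RasterLayer,
    params: dict,
    class_codes: dict,
    biomass_adjustment: float = 0.0,
) -> RasterLayer:
    """Assemble the annual metabolizable-energy-content raster (MJ/ha/year).

    Per vegetated pixel:
    ``MEC = max(standing - adjustment, 0) * productivity_ratio * consumable_fraction
    * forage_quality`` with the community's parameters; non-vegetated classes
    (any class code absent from ``class_codes``) contribute 0; nodata in
    either input propagates to nodata.  ``biomass_adjustment`` (kg DM/ha,
    subtracted before the productivity ratio) implements conservative-supply
    scenarios that discount the biomass model's absolute error.
    """
    standing_biomass.require_grid(communities, "community raster")
    missing = [cid for cid in class_codes.values() if cid not in params]
    if missing:
        raise ConfigError(f"no community parameters for class(es): {sorted(set(missing))}")

    biomass = standing_biomass.filled(np.nan)
    cls = communities.data
    cls_valid = communities.mask_valid()
    mec = np.zeros(standing_biomass.shape, dtype=float)
    adjusted = np.maximum(biomass - biomass_adjustment, 0.0)
    for code, cid in class_codes.items():
        p = params[cid]
        sel = cls_valid & (cls == code)
        mec[sel] = (
            adjusted[sel] * p.productivity_ratio * p.consumable_fraction * p.forage_quality
        )
    mec[~np.isfinite(biomass) | ~cls_valid] = np.nan
    return standing_biomass.with_data(mec.astype(np.float32), units="MJ/ha/yr")
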