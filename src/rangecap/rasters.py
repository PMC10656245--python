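"""Minimal georeferenced raster container and GeoTIFF I/O.

All rasters in the pipeline live on north-up, square-pixel grids in a single
projected CRS with metre units.  A :class:`RasterLayer` couples a 2-D numpy
array with the affine pieces that matter here (origin, pixel size), a CRS
string, an explicit nodata value and a free-form ``units`` tag so that layers
with incompatible semantics (kg DM/ha vs. % FSC vs. m a.s.l.) cannot be mixed
silently.

Files are written as GeoTIFF: the georeferencing goes into the standard
ModelPixelScale / ModelTiepoint tags, nodata into the GDAL_NODATA tag, and the
CRS / units into a JSON ImageDescription.  tifffile handles the container
format; this module only owns the tag semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = ["RasterLayer", "read_raster", "write_raster", "GridMismatchError"]

# GeoTIFF / GDAL private tags
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridMismatchError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass
class RasterLayer:
    """A single-band raster on a north-up square-pixel grid.

    Parameters
    ----------
    data
        2-D array, row 0 at the northern edge.
    x_origin, y_origin
        Projected coordinates of the *outer* top-left corner of pixel (0, 0).
    pixel_size
        Edge length of a pixel in CRS units (metres), > 0.
    crs
        CRS identifier, e.g. ``"EPSG:32643"``.
    nodata
        Value marking missing pixels (may be NaN for float rasters).
    units
        Semantic tag, e.g. ``"kg DM/ha"``, ``"% FSC"``, ``"m"``, ``"class"``.
    """

    data: np.ndarray
    x_origin: float
    y_origin: float
    pixel_size: float
    crs: str = "EPSG:32643"
    nodata: float = float("nan")
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {self.data.shape}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    # -- grid geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pixel_area_ha(self) -> float:
        """Area of one pixel in hectares (1 ha = 10 000 m2)."""
        return self.pixel_size**2 / 10_000.0

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) coordinates of every pixel center, as 2-D grids."""
        rows, cols = self.shape
        xs = self.x_origin + (np.arange(cols) + 0.5) * self.pixel_size
        ys = self.y_origin - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the pixels containing projected points."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.pixel_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col

    def same_grid(self, other: "RasterLayer") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.pixel_size, other.pixel_size)
            and self.crs == other.crs
        )

    def require_grid(self, other: "RasterLayer", what: str = "raster") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} is not co-registered: "
                f"{other.shape}@{other.pixel_size} m vs {self.shape}@{self.pixel_size} m "
                f"(CRS {other.crs} vs {self.crs})"
            )

    # -- nodata handling -----------------------------------------------

    def mask_valid(self) -> np.ndarray:
        """Boolean array, True where the pixel carries a value."""
        if isinstance(self.nodata, float) and np.isnan(self.nodata):
            return ~np.isnan(self.data.astype(float))
        return self.data != self.nodata

    def filled(self, fill: float = np.nan) -> np.ndarray:
        """Data as float with nodata replaced by ``fill``."""
        out = self.data.astype(float).copy()
        out[~self.mask_valid()] = fill
        return out

    def with_data(self, data: np.ndarray, units: str | None = None) -> "RasterLayer":
        """A new layer on the same grid carrying different values."""
        layer = replace(self, data=np.asarray(data))
        if units is not None:
            layer.units = units
        return layer


def write_raster(path, layer: RasterLayer) -> None:
    """Write a :class:`RasterLayer` as a single-band GeoTIFF."""
    data = layer.data
    if data.dtype not in (np.uint8, np.int16, np.int32, np.float32):
        data = data.astype(np.float32)
    desc = json.dumps({"crs": layer.crs, "units": layer.units})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (layer.pixel_size, layer.pixel_size, 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, layer.x_origin, layer.y_origin, 0.0),
        ),
    ]
    # NaN nodata is the read-side default; writing it as text trips GDAL-tag
    # parsers, so only finite sentinels are recorded explicitly
    if not (isinstance(layer.nodata, float) and np.isnan(layer.nodata)):
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(layer.nodata)))
    tifffile.imwrite(path, data, description=desc, extratags=extratags)


def read_raster(path) -> RasterLayer:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        try:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags") from exc
        nodata = float("nan")
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        crs, units = "", ""
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                crs = meta.get("crs", "")
                units = meta.get("units", "")
            except (json.JSONDecodeError, AttributeError):
                pass
    return RasterLayer(
        data=data,
        x_origin=float(tiepoint[3]),
        y_origin=float(tiepoint[4]),
        pixel_size=float(scale[0]),
        crs=crs,
        nodata=nodata,
        units=units,
    )
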