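"""Raster and vector data model for gridded-population sampling frames.

All geometry conventions live here.  A :class:`PopulationGrid` is a
row-major raster with its origin at the *top-left* corner; the row index
increases southward.  Cell extents are half-open, ``[x_min, x_max) x
(y_min, y_max]``, so adjacent units never double-count cells.  Only
projected, metre-unit coordinate reference systems are accepted —
reprojection is the caller's job.

Rasters are read and written as single-band GeoTIFFs (via :mod:`tifffile`,
which handles the GeoTIFF ModelPixelScale / ModelTiepoint / GeoKeyDirectory
tags).  Boundary polygons travel as GeoJSON FeatureCollections with a
required ``region_id`` property.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

__all__ = [
    "Extent",
    "PopulationGrid",
    "RegionSet",
    "load_population_grid",
    "write_population_grid",
    "mask_grid",
    "grid_total",
    "load_regions",
    "write_regions",
]

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

_GEOKEY_MODEL_TYPE = 1024
_GEOKEY_RASTER_TYPE = 1025
_GEOKEY_PROJECTED_CS = 3072
_MODEL_PROJECTED = 1
_MODEL_GEOGRAPHIC = 2


@dataclass(frozen=True)
class Extent:
    """Axis-aligned bounding box in projected CRS metres."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate extent {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def to_polygon(self) -> BaseGeometry:
        return shapely.box(self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass
class PopulationGrid:
    """A 2-D raster of non-negative population counts with geotransform.

    ``values`` holds persons per cell; ``mask`` is True for cells inside
    the study area.  Masked-out cells carry value 0 and contribute nothing
    to any sum.  ``origin_x``/``origin_y`` are the CRS coordinates of the
    grid's top-left corner.
    """

    values: np.ndarray
    cell_size: float
    origin_x: float
    origin_y: float
    crs_id: str = "EPSG:32638"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        inside = self.values[self.mask]
        if inside.size and (not np.all(np.isfinite(inside)) or np.any(inside < 0)):
            raise ValueError("masked-in values must be finite and >= 0")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> Extent:
        return Extent(
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, each shaped (n_rows, n_cols)."""
        cs = self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * cs
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def masked_values(self) -> np.ndarray:
        """Values with masked-out cells zeroed (the array all sums run over)."""
        return np.where(self.mask, self.values, 0.0)

    def copy(self) -> "PopulationGrid":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())


@dataclass
class RegionSet:
    """Named polygons of one role: admin regions, urban EAs or IDP camps."""

    polygons: list[tuple[str, BaseGeometry]]
    role: str = "admin"

    def __post_init__(self) -> None:
        if self.role not in {"admin", "urban", "idp"}:
            raise ValueError(f"unknown role {self.role!r}")
        ids = [rid for rid, _ in self.polygons]
        if len(ids) != len(set(ids)):
            raise ValueError("region_ids must be unique")
        repaired = []
        for rid, geom in self.polygons:
            if not geom.is_valid:
                geom = make_valid(geom)
            repaired.append((rid, geom))
        self.polygons = repaired

    def __iter__(self):
        return iter(self.polygons)

    def __len__(self) -> int:
        return len(self.polygons)

    @property
    def region_ids(self) -> list[str]:
        return [rid for rid, _ in self.polygons]

    def union(self) -> BaseGeometry:
        return shapely.union_all([g for _, g in self.polygons])


def load_population_grid(path: str | Path) -> PopulationGrid:
    """Read a single-band projected GeoTIFF into a :class:`PopulationGrid`.

    Nodata cells are masked out and their value set to 0.  Rasters in a
    geographic (degree-unit) CRS or with non-square cells are rejected.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        geo = page.geotiff_tags
        if geo is None:
            raise ValueError(f"{path}: no GeoTIFF georeferencing tags")
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = nodata_tag.value if nodata_tag is not None else None

    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {values.shape}")

    model_type = int(geo.get("GTModelTypeGeoKey", 0))
    if model_type == _MODEL_GEOGRAPHIC or "GeographicTypeGeoKey" in geo:
        raise ValueError(
            f"{path}: raster is in a geographic (degree) CRS; "
            "reproject to a projected metre-unit CRS first"
        )
    scale = geo.get("ModelPixelScale")
    tiepoint = geo.get("ModelTiepoint")
    if scale is None or tiepoint is None:
        raise ValueError(f"{path}: missing ModelPixelScale/ModelTiepoint tags")
    sx, sy = float(scale[0]), float(scale[1])
    if not np.isclose(sx, sy, rtol=1e-9):
        raise ValueError(f"{path}: non-square cells ({sx} x {sy} m) are not supported")
    # tiepoint maps raster (i, j, k) -> model (x, y, z); anchor must be the corner
    i, j = float(tiepoint[0]), float(tiepoint[1])
    origin_x = float(tiepoint[3]) - i * sx
    origin_y = float(tiepoint[4]) + j * sy

    epsg = geo.get("ProjectedCSTypeGeoKey")
    crs_id = f"EPSG:{int(epsg)}" if epsg is not None else "projected-unspecified"

    values = np.asarray(values, dtype=np.float64)
    mask = np.isfinite(values)
    if nodata is not None:
        try:
            nd = float(nodata)
        except (TypeError, ValueError):
            nd = np.nan
        if np.isnan(nd):
            mask &= ~np.isnan(values)
        else:
            mask &= values != nd
    if np.any(values[mask] < 0):
        raise ValueError(f"{path}: negative population values present")
    values = np.where(mask, values, 0.0)
    return PopulationGrid(values, sx, origin_x, origin_y, crs_id=crs_id, mask=mask)


def write_population_grid(grid: PopulationGrid, path: str | Path) -> Path:
    """Write a grid as a float64 GeoTIFF; masked-out cells become NaN nodata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = np.where(grid.mask, grid.values, np.nan)
    geokeys = [
        _GEOKEY_MODEL_TYPE, 0, 1, _MODEL_PROJECTED,
        _GEOKEY_RASTER_TYPE, 0, 1, 1,
    ]
    if grid.crs_id.upper().startswith("EPSG:"):
        geokeys += [_GEOKEY_PROJECTED_CS, 0, 1, int(grid.crs_id.split(":")[1])]
    header = [1, 1, 0, len(geokeys) // 4]
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0), True),
        (_TAG_GEOKEYS, "H", len(header) + len(geokeys), tuple(header + geokeys), True),
        (_TAG_GDAL_NODATA, "s", 0, "nan", True),
    ]
    tifffile.imwrite(path, out, extratags=extratags)
    return path


def mask_grid(grid: PopulationGrid, region: BaseGeometry) -> PopulationGrid:
    """Restrict a grid to the cells whose centre falls inside ``region``.

    The grid extent is unchanged; outside cells are masked out and zeroed.
    An empty intersection yields an all-false mask with a warning.
    """
    xs, ys = grid.cell_centres()
    inside = shapely.intersects_xy(region, xs.ravel(), ys.ravel()).reshape(grid.values.shape)
    new_mask = grid.mask & inside
    if not new_mask.any():
        warnings.warn("polygon does not cover any masked-in cell centre", stacklevel=2)
    return replace(
        grid,
        values=np.where(new_mask, grid.values, 0.0),
        mask=new_mask,
    )


def grid_total(grid: PopulationGrid) -> float:
    """Total population over masked-in cells."""
    return float(grid.values[grid.mask].sum())


def load_regions(path: str | Path, role: str = "admin") -> RegionSet:
    """Read a GeoJSON FeatureCollection with ``region_id`` properties."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    polys = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if "region_id" not in props:
            raise ValueError(f"{path}: feature missing required 'region_id' property")
        polys.append((str(props["region_id"]), geom_shape(feat["geometry"])))
    return RegionSet(polys, role=role)


def write_regions(regions: RegionSet, path: str | Path,
                  extra_properties: dict[str, dict] | None = None) -> Path:
    """Write a RegionSet as a GeoJSON FeatureCollection."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    feats = []
    for rid, geom in regions:
        props = {"region_id": rid, "role": regions.role}
        if extra_properties and rid in extra_properties:
            props.update(extra_properties[rid])
        feats.append({"type": "Feature", "properties": props,
                      "geometry": geom_mapping(geom)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
    return path
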