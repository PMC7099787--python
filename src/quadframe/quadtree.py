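"""Quadtree decomposition of a population grid into sampling units.

The frame-building step at the heart of the package: starting from a square
root window that covers the (masked, usually smoothed) raster, each window
is split into four quadrants — depth-first in NW, NE, SW, SE order — until
it satisfies both a population ceiling (``pop_max``, production value 3500
persons) and an area ceiling (``side_max_m``, production value 3000 m).
The result is a spatially complete set of square-ish units: small where
people are dense, large where they are sparse, which is what makes the
frame approximately population-homogeneous.

Root-window convention.  When ``side_max_cells < max(n_rows, n_cols)`` the
grid is padded (zero population, masked out) to a square of side
``side_max_cells * 2**m`` cells, the smallest such covering the grid; the
area ceiling then binds at *exactly* ``side_max_m`` (e.g. 3 x 3 km leaves
on a 100 m raster).  When the whole grid already fits within the area
ceiling, plain power-of-two padding (smallest ``2**b`` covering the grid)
is used instead, so quadrants halve evenly.  Odd window sides split at
``floor(side / 2)``, giving quadrants square up to one cell of asymmetry.
Units wholly in padding (or containing no masked-in cell) are dropped;
units that overlap the valid mask are kept whole, their population summed
over valid cells only — zero-population units are retained in the frame.
A single cell at or above ``pop_max`` cannot be split further: it is
emitted as a leaf flagged ``over_threshold``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from math import floor
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .grid_model import Extent, PopulationGrid

__all__ = ["QuadtreeSpec", "FrameUnit", "Frame", "quadtree_partition"]


@dataclass(frozen=True)
class QuadtreeSpec:
    """Stopping rules for the decomposition.

    pop_max: split while a unit holds this many persons or more (3500).
    side_max_m: maximum unit side in metres (3000, i.e. 3 x 3 km).
    min_side_cells: smallest splittable side, in cells.
    """

    pop_max: float = 3500.0
    side_max_m: float = 3000.0
    min_side_cells: int = 1

    def __post_init__(self) -> None:
        if self.pop_max <= 0:
            raise ValueError("pop_max must be positive")
        if self.min_side_cells < 1:
            raise ValueError("min_side_cells must be >= 1")

    def side_max_cells(self, cell_size: float) -> int:
        n = floor(self.side_max_m / cell_size)
        if n < 1:
            raise ValueError(
                f"side_max_m {self.side_max_m} is below one cell ({cell_size} m)"
            )
        return n


@dataclass(frozen=True)
class FrameUnit:
    """One sampling unit: a square-ish window with its population."""

    unit_id: str
    extent: Extent
    side_m: float
    population: float
    stratum_id: str = ""
    n_cells_valid: int = 0
    over_threshold: bool = False


@dataclass
class Frame:
    """An ordered, non-overlapping collection of sampling units."""

    units: list[FrameUnit]
    method: str = "quadtree"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValueError("unit_ids must be unique within a frame")

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self) -> Iterator[FrameUnit]:
        return iter(self.units)

    @property
    def populations(self) -> np.ndarray:
        return np.array([u.population for u in self.units], dtype=np.float64)

    def total_population(self) -> float:
        return float(self.populations.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": [u.unit_id for u in self.units],
                "stratum_id": [u.stratum_id for u in self.units],
                "x_min": [u.extent.x_min for u in self.units],
                "y_min": [u.extent.y_min for u in self.units],
                "x_max": [u.extent.x_max for u in self.units],
                "y_max": [u.extent.y_max for u in self.units],
                "side_m": [u.side_m for u in self.units],
                "population": [u.population for u in self.units],
                "n_cells_valid": [u.n_cells_valid for u in self.units],
                "over_threshold": [u.over_threshold for u in self.units],
            }
        )

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False)
        return path

    def write_geojson(self, path: str | Path) -> Path:
        import json

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        feats = []
        for u in self.units:
            e = u.extent
            ring = [
                [e.x_min, e.y_min], [e.x_max, e.y_min],
                [e.x_max, e.y_max], [e.x_min, e.y_max], [e.x_min, e.y_min],
            ]
            feats.append(
                {
                    "type": "Feature",
                    "properties": {
                        "unit_id": u.unit_id,
                        "stratum_id": u.stratum_id,
                        "side_m": u.side_m,
                        "population": u.population,
                        "n_cells_valid": u.n_cells_valid,
                        "over_threshold": u.over_threshold,
                    },
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
        return path


def _grid_checksum(grid: PopulationGrid) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(grid.values).tobytes())
    h.update(np.ascontiguousarray(grid.mask).tobytes())
    h.update(np.array([grid.cell_size, grid.origin_x, grid.origin_y]).tobytes())
    return h.hexdigest()[:16]


def _root_side_cells(n_rows: int, n_cols: int, side_max_cells: int) -> int:
    """Smallest admissible square root window covering the grid."""
    maxdim = max(n_rows, n_cols)
    if side_max_cells >= maxdim:
        side = 1
        while side < maxdim:
            side *= 2
        return side
    side = side_max_cells
    while side < maxdim:
        side *= 2
    return side


def quadtree_partition(
    grid: PopulationGrid, spec: QuadtreeSpec, stratum_id: str = ""
) -> Frame:
    """Partition a masked grid into quadtree sampling units.

    Returns units in deterministic depth-first NW, NE, SW, SE order; an
    empty mask yields an empty frame.  The sum of unit populations equals
    the grid total (same cells, same summation).
    """
    side_max_cells = spec.side_max_cells(grid.cell_size)
    prov = {
        "method": "quadtree",
        "pop_max": spec.pop_max,
        "side_max_m": spec.side_max_m,
        "min_side_cells": spec.min_side_cells,
        "input_checksum": _grid_checksum(grid),
    }
    if not grid.mask.any():
        return Frame([], method="quadtree", provenance=prov)

    vm = grid.masked_values()
    mask_i = grid.mask.astype(np.int64)
    n_rows, n_cols = vm.shape
    cs = grid.cell_size
    root = _root_side_cells(n_rows, n_cols, side_max_cells)
    prefix = f"{stratum_id}:" if stratum_id else ""

    units: list[FrameUnit] = []

    def emit(r0: int, c0: int, nr: int, nc: int, path: str) -> None:
        # clip to the raster for sums; the unit extent stays whole
        r1, c1 = r0 + nr, c0 + nc
        rc0, cc0 = min(r0, n_rows), min(c0, n_cols)
        rc1, cc1 = min(r1, n_rows), min(c1, n_cols)
        if rc0 >= rc1 or cc0 >= cc1:
            return  # wholly in padding
        n_valid = int(mask_i[rc0:rc1, cc0:cc1].sum())
        if n_valid == 0:
            return
        pop = float(vm[rc0:rc1, cc0:cc1].sum())
        side_cells = max(nr, nc)
        splittable = side_cells > spec.min_side_cells
        fits = pop < spec.pop_max and side_cells <= side_max_cells
        if fits or not splittable:
            units.append(
                FrameUnit(
                    unit_id=f"{prefix}q{path}",
                    extent=Extent(
                        grid.origin_x + c0 * cs,
                        grid.origin_y - r1 * cs,
                        grid.origin_x + c1 * cs,
                        grid.origin_y - r0 * cs,
                    ),
                    side_m=side_cells * cs,
                    population=pop,
                    stratum_id=stratum_id,
                    n_cells_valid=n_valid,
                    over_threshold=pop >= spec.pop_max,
                )
            )
            return
        hr, hc = nr // 2, nc // 2
        # NW, NE, SW, SE
        emit(r0, c0, hr, hc, path + "0")
        emit(r0, c0 + hc, hr, nc - hc, path + "1")
        emit(r0 + hr, c0, nr - hr, hc, path + "2")
        emit(r0 + hr, c0 + hc, nr - hr, nc - hc, path + "3")

    emit(0, 0, root, root, "")
    return Frame(units, method="quadtree", provenance=prov)
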