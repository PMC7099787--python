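"""Uniform-grid-cell baseline frames and frame-quality diagnostics.

The conventional gridded-survey frame tiles the country with fixed-size
square cells (UGC, e.g. 1 x 1 km or 3 x 3 km) regardless of where people
live.  ``ugc_partition`` builds that baseline; ``frame_metrics`` computes
the population-homogeneity summaries (min, max, mean, std, cv) used to
compare it against a quadtree frame, nationally and within admin regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .grid_model import Extent, PopulationGrid, RegionSet
from .quadtree import Frame, FrameUnit, _grid_checksum

__all__ = ["FrameMetrics", "ugc_partition", "frame_metrics", "metrics_to_dataframe"]


@dataclass(frozen=True)
class FrameMetrics:
    """Population summary of the units in one scope (national or one region)."""

    scope_id: str
    n_units: int
    min: float
    max: float
    mean: float
    std: float
    cv: float  # std / mean; NaN when mean is 0 or no units


def ugc_partition(grid: PopulationGrid, side_m: float, stratum_id: str = "") -> Frame:
    """Tile the grid with uniform square cells of side ``side_m``.

    The tiling is anchored at the grid origin; partial tiles at the east
    and south edges are retained; tiles containing no masked-in cell are
    dropped.  ``side_m`` must be an integer multiple of the cell size.
    """
    ratio = side_m / grid.cell_size
    side_cells = int(round(ratio))
    if side_cells < 1 or not math.isclose(ratio, side_cells, rel_tol=1e-9):
        raise ValueError(
            f"side_m {side_m} is not an integer multiple of cell size {grid.cell_size}"
        )
    vm = grid.masked_values()
    mask_i = grid.mask.astype(np.int64)
    n_rows, n_cols = vm.shape
    row_edges = np.arange(0, n_rows, side_cells)
    col_edges = np.arange(0, n_cols, side_cells)
    pops = np.add.reduceat(np.add.reduceat(vm, row_edges, axis=0), col_edges, axis=1)
    counts = np.add.reduceat(
        np.add.reduceat(mask_i, row_edges, axis=0), col_edges, axis=1
    )
    cs = grid.cell_size
    prefix = f"{stratum_id}:" if stratum_id else ""
    units = []
    for ti, r0 in enumerate(row_edges):
        r1 = min(r0 + side_cells, n_rows)
        for tj, c0 in enumerate(col_edges):
            if counts[ti, tj] == 0:
                continue
            c1 = min(c0 + side_cells, n_cols)
            units.append(
                FrameUnit(
                    unit_id=f"{prefix}ugc_{ti}_{tj}",
                    extent=Extent(
                        grid.origin_x + c0 * cs,
                        grid.origin_y - r1 * cs,
                        grid.origin_x + c1 * cs,
                        grid.origin_y - r0 * cs,
                    ),
                    side_m=max(r1 - r0, c1 - c0) * cs,
                    population=float(pops[ti, tj]),
                    stratum_id=stratum_id,
                    n_cells_valid=int(counts[ti, tj]),
                )
            )
    prov = {"method": "ugc", "side_m": side_m, "input_checksum": _grid_checksum(grid)}
    return Frame(units, method="ugc", provenance=prov)


def _summary(scope_id: str, pops: np.ndarray) -> FrameMetrics:
    if pops.size == 0:
        return FrameMetrics(scope_id, 0, math.nan, math.nan, math.nan, math.nan, math.nan)
    mean = float(pops.mean())
    std = float(pops.std(ddof=0))
    cv = std / mean if mean > 0 else math.nan
    return FrameMetrics(scope_id, int(pops.size), float(pops.min()),
                        float(pops.max()), mean, std, cv)


def frame_metrics(frame: Frame, regions: RegionSet | None = None) -> list[FrameMetrics]:
    """Homogeneity diagnostics: one national row, plus one row per region.

    The standard deviation uses the population (ddof 0) denominator and
    cv = std / mean.  When ``regions`` is given, each unit is assigned by
    its centroid; centroids on a shared boundary go to the lowest
    region_id.  A region containing no unit centroid gets a row with
    n_units 0 and NaN statistics.
    """
    if len(frame) == 0:
        raise ValueError("frame is empty")
    pops = frame.populations
    rows = [_summary("national", pops)]
    if regions is not None:
        cx = np.array([(u.extent.x_min + u.extent.x_max) / 2 for u in frame])
        cy = np.array([(u.extent.y_min + u.extent.y_max) / 2 for u in frame])
        assigned = np.full(len(frame), -1)
        order = sorted(range(len(regions)), key=lambda i: regions.polygons[i][0])
        for ri in order:
            _, geom = regions.polygons[ri]
            todo = assigned < 0
            if not todo.any():
                break
            hit = shapely.intersects_xy(geom, cx[todo], cy[todo])
            idx = np.flatnonzero(todo)[hit]
            assigned[idx] = ri
        for ri, (rid, _) in enumerate(regions.polygons):
            rows.append(_summary(rid, pops[assigned == ri]))
    return rows


def metrics_to_dataframe(rows: list[FrameMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scope_id": [r.scope_id for r in rows],
            "n_units": [r.n_units for r in rows],
            "min": [r.min for r in rows],
            "max": [r.max for r in rows],
            "mean": [r.mean for r in rows],
            "std": [r.std for r in rows],
            "cv": [r.cv for r in rows],
        }
    )


def write_metrics_csv(rows: list[FrameMetrics], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metrics_to_dataframe(rows).to_csv(path, index=False)
    return path
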