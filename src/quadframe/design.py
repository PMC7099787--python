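"""Stratification and Neyman optimal allocation.

Design strata are the intersection of admin regions with population type
(urban, rural, IDP): within each region the IDP stratum is the region cut
to the IDP camp polygons, the urban stratum is the region cut to the urban
EA polygons minus any IDP overlap, and the rural stratum is the remainder.
The total sample is then shared across strata by Neyman allocation,

    n_h = n * N_h S_h / sum_h N_h S_h,

which minimises the variance of the estimated mean for a fixed total
sample size n: strata that are large (N_h) or internally variable in the
target outcome (S_h, e.g. the consumption standard deviation) receive more
primary sampling units.  A floor (default two PSUs per stratum) keeps
stratum-level variance estimable, and explicit per-stratum overrides
express deliberate oversampling of populations of special interest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .grid_model import RegionSet

__all__ = ["StratumSpec", "Allocation", "StratumPolygon", "stratify", "neyman_allocate"]

_AREA_TOL = 1e-9  # relative area below which an intersection piece is "empty"


@dataclass(frozen=True)
class StratumSpec:
    """Allocation inputs for one stratum.

    N_h is the stratum population (persons or households — consistent
    across strata); S_h the outcome standard deviation in that stratum;
    ``oversample_override`` pins the allocation to a fixed PSU count.
    """

    stratum_id: str
    region_id: str = ""
    pop_type: str = "rural"
    N_h: float = 0.0
    S_h: float = 1.0
    oversample_override: int | None = None

    def __post_init__(self) -> None:
        if self.N_h < 0 or self.S_h < 0:
            raise ValueError("N_h and S_h must be >= 0")
        if self.pop_type not in {"urban", "rural", "idp"}:
            raise ValueError(f"unknown pop_type {self.pop_type!r}")


class Allocation(NamedTuple):
    stratum_id: str
    n_h: int


class StratumPolygon(NamedTuple):
    stratum_id: str
    region_id: str
    pop_type: str
    geometry: BaseGeometry


def stratify(
    admin: RegionSet, urban: RegionSet | None = None, idp: RegionSet | None = None
) -> list[StratumPolygon]:
    """Cut each admin region into idp / urban / rural strata.

    Within a region: idp = region ∩ idp camps; urban = region ∩ urban EAs
    minus idp; rural = region minus (urban ∪ idp).  Empty pieces are
    dropped.  Overlapping admin regions are an error.
    """
    geoms = admin.polygons
    offenders = []
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            inter = geoms[i][1].intersection(geoms[j][1]).area
            if inter > _AREA_TOL * min(geoms[i][1].area, geoms[j][1].area):
                offenders.append((geoms[i][0], geoms[j][0]))
    if offenders:
        raise ValueError(f"overlapping admin regions: {offenders}")

    urban_u = urban.union() if urban is not None and len(urban) else None
    idp_u = idp.union() if idp is not None and len(idp) else None

    strata: list[StratumPolygon] = []
    for rid, region in geoms:
        remaining = region
        if idp_u is not None:
            piece = region.intersection(idp_u)
            if piece.area > _AREA_TOL * region.area:
                strata.append(StratumPolygon(f"{rid}_idp", rid, "idp", piece))
            remaining = remaining.difference(idp_u)
        if urban_u is not None:
            piece = remaining.intersection(urban_u)
            if piece.area > _AREA_TOL * region.area:
                strata.append(StratumPolygon(f"{rid}_urban", rid, "urban", piece))
            remaining = remaining.difference(urban_u)
        if remaining.area > _AREA_TOL * region.area:
            strata.append(StratumPolygon(f"{rid}_rural", rid, "rural", remaining))
    return strata


def _largest_remainder(sizes: dict[str, float], n: int) -> dict[str, int]:
    """Proportional integerisation; ties broken by stratum_id order."""
    total = sum(sizes.values())
    raw = {sid: n * v / total for sid, v in sizes.items()}
    base = {sid: math.floor(r) for sid, r in raw.items()}
    leftover = n - sum(base.values())
    by_frac = sorted(sizes, key=lambda sid: (-(raw[sid] - base[sid]), sid))
    for sid in by_frac[:leftover]:
        base[sid] += 1
    return base


def neyman_allocate(
    strata: list[StratumSpec], n_total: int, min_per_stratum: int = 2
) -> list[Allocation]:
    """Share ``n_total`` PSUs across strata in proportion to N_h * S_h.

    Overrides are honoured exactly; the remainder is integerised by
    largest remainder; strata falling below ``min_per_stratum`` are raised
    to the floor and the excess re-shared proportionally among the rest.
    """
    ids = [s.stratum_id for s in strata]
    if len(ids) != len(set(ids)):
        raise ValueError("stratum_ids must be unique")
    fixed: dict[str, int] = {
        s.stratum_id: int(s.oversample_override)
        for s in strata
        if s.oversample_override is not None
    }
    free = [s for s in strata if s.stratum_id not in fixed]
    n_free = n_total - sum(fixed.values())
    if n_free < min_per_stratum * len(free):
        raise ValueError(
            f"n_total {n_total} cannot give every one of {len(free)} "
            f"non-override strata at least {min_per_stratum} PSUs "
            f"(overrides take {sum(fixed.values())})"
        )

    alloc: dict[str, int] = dict(fixed)
    if free:
        sizes = {s.stratum_id: s.N_h * s.S_h for s in free}
        if all(v == 0 for v in sizes.values()):
            warnings.warn(
                "all N_h * S_h are zero among non-override strata; "
                "falling back to equal shares",
                stacklevel=2,
            )
            sizes = {sid: 1.0 for sid in sizes}
        pool = dict(sizes)
        floored: dict[str, int] = {}
        budget = n_free
        while True:
            if not pool:
                # everything hit the floor; share any leftover proportionally
                if budget > sum(floored.values()) and floored:
                    extra = budget - sum(floored.values())
                    top_up = _largest_remainder(
                        {sid: sizes[sid] if sizes[sid] > 0 else 1.0 for sid in floored},
                        extra,
                    )
                    for sid, t in top_up.items():
                        floored[sid] += t
                share = {}
                break
            share = _largest_remainder(pool, budget - sum(floored.values()))
            deficient = [sid for sid, a in share.items() if a < min_per_stratum]
            if not deficient:
                break
            for sid in deficient:
                floored[sid] = min_per_stratum
                del pool[sid]
        alloc.update(floored)
        alloc.update(share)

    out = [Allocation(s.stratum_id, alloc[s.stratum_id]) for s in strata]
    assert sum(a.n_h for a in out) == n_total
    return out


def read_strata_csv(path: str | Path) -> list[StratumSpec]:
    """Strata table: stratum_id, region_id, pop_type, N_h, S_h, override."""
    df = pd.read_csv(path)
    specs = []
    for _, row in df.iterrows():
        override = row.get("override")
        if override is None or (isinstance(override, float) and math.isnan(override)):
            override = None
        else:
            override = int(override)
        specs.append(
            StratumSpec(
                stratum_id=str(row["stratum_id"]),
                region_id=str(row.get("region_id", "")),
                pop_type=str(row.get("pop_type", "rural")),
                N_h=float(row["N_h"]),
                S_h=float(row["S_h"]),
                oversample_override=override,
            )
        )
    return specs


def write_allocation_csv(allocations: list[Allocation], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(allocations, columns=["stratum_id", "n_h"]).to_csv(path, index=False)
    return path
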