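"""Config-driven end-to-end run: raster to design weights.

Stages, in order: inputs (load or synthesise), smooth, stratify, frames
(quadtree per stratum plus UGC baselines and homogeneity metrics),
allocate, sample, weights.  Every stage writes its artifacts under the
output directory and appends an entry to the run manifest (parameters,
derived seeds, input checksums, row counts), so a run can be audited and
re-entered at any stage, and rerunning with the same config reproduces
byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import design, frames, grid_model, quadtree, sampling, smoothing, synthetic, weights
from .grid_model import PopulationGrid, RegionSet
from .quadtree import Frame

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Flat key-value run configuration with the production defaults baked in.

    The defaults reproduce the production parameterisation: 500 m
    smoothing, 3500-person / 3 x 3 km quadtree limits, UGC baselines of
    1 and 3 km, 6384 total sample, minimum two PSUs per stratum, 20%
    replacement sample.
    """

    out_dir: str = "run_output"
    master_seed: int = 0
    # inputs: either synthetic geometry ...
    synthetic: bool = True
    n_rows: int = 512
    n_cols: int = 512
    cell_size: float = 100.0
    n_clusters: int = 12
    background_density: float = 0.02
    n_regions: int = 4
    urban_radius_m: float = 2000.0
    # ... or paths to pre-existing data
    raster_path: str | None = None
    admin_path: str | None = None
    urban_path: str | None = None
    idp_path: str | None = None
    # smoothing
    sigma_m: float = 500.0
    truncation_radius_sigmas: float = 4.0
    # quadtree / UGC
    pop_max: float = 3500.0
    side_max_m: float = 3000.0
    ugc_sides_m: list[float] = field(default_factory=lambda: [1000.0, 3000.0])
    # allocation
    n_total: int = 6384
    min_per_stratum: int = 2
    s_h: dict[str, float] | float = 1.0
    overrides: dict[str, int] = field(default_factory=dict)
    # selection & weights
    replacement_rate: float = 0.2
    exclude_unit_ids: list[str] = field(default_factory=list)
    mean_household_size: float = 5.37

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _stratum_s_h(config: RunConfig, stratum_id: str) -> float:
    if isinstance(config.s_h, dict):
        return float(config.s_h.get(stratum_id, 1.0))
    return float(config.s_h)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in vars(config).items()}, "stages": []}
    stage_name = "inputs"

    def done(name: str, **info) -> None:
        manifest["stages"].append({"name": name, **info})
        logger.info("stage %s complete: %s", name, info)

    try:
        # ---- inputs -------------------------------------------------
        if config.synthetic:
            spec = synthetic.random_clustered_spec(
                seed=config.master_seed,
                n_rows=config.n_rows,
                n_cols=config.n_cols,
                cell_size=config.cell_size,
                n_clusters=config.n_clusters,
                background_density=config.background_density,
                n_regions=config.n_regions,
                urban_radius_m=config.urban_radius_m,
            )
            grid = synthetic.make_population_raster(spec)
            admin, urban, idp = synthetic.make_boundaries(spec)
            grid_model.write_population_grid(grid, out / "population.tif")
            grid_model.write_regions(admin, out / "admin.geojson")
            grid_model.write_regions(urban, out / "urban.geojson")
            grid_model.write_regions(idp, out / "idp.geojson")
        else:
            if not config.raster_path or not config.admin_path:
                raise ValueError("raster_path and admin_path are required")
            grid = grid_model.load_population_grid(config.raster_path)
            admin = grid_model.load_regions(config.admin_path, role="admin")
            urban = (grid_model.load_regions(config.urban_path, role="urban")
                     if config.urban_path else RegionSet([], role="urban"))
            idp = (grid_model.load_regions(config.idp_path, role="idp")
                   if config.idp_path else RegionSet([], role="idp"))
        done("inputs",
             total_population=round(grid_model.grid_total(grid), 3),
             n_rows=grid.n_rows, n_cols=grid.n_cols,
             input_checksum=quadtree._grid_checksum(grid))

        # ---- smooth -------------------------------------------------
        stage_name = "smooth"
        sspec = smoothing.SmoothingSpec(config.sigma_m, config.truncation_radius_sigmas)
        smoothed = smoothing.gaussian_smooth(grid, sspec)
        grid_model.write_population_grid(smoothed, out / "smoothed.tif")
        done("smooth", sigma_m=config.sigma_m,
             total_population=round(grid_model.grid_total(smoothed), 3))

        # ---- stratify -----------------------------------------------
        stage_name = "stratify"
        strata_polys = design.stratify(admin, urban, idp)
        strat_regions = RegionSet(
            [(s.stratum_id, s.geometry) for s in strata_polys], role="admin"
        )
        grid_model.write_regions(strat_regions, out / "strata.geojson")
        done("stratify", n_strata=len(strata_polys))

        # ---- frames -------------------------------------------------
        stage_name = "frames"
        qspec = quadtree.QuadtreeSpec(config.pop_max, config.side_max_m)
        units = []
        stratum_totals: dict[str, float] = {}
        for s in strata_polys:
            sub = grid_model.mask_grid(smoothed, s.geometry)
            stratum_totals[s.stratum_id] = grid_model.grid_total(sub)
            sub_frame = quadtree.quadtree_partition(sub, qspec, stratum_id=s.stratum_id)
            units.extend(sub_frame.units)
        frame = Frame(units, method="quadtree",
                      provenance={"pop_max": config.pop_max,
                                  "side_max_m": config.side_max_m,
                                  "stratified": True})
        frame.write_csv(out / "frame_quadtree.csv")
        frame.write_geojson(out / "frame_quadtree.geojson")
        frames.write_metrics_csv(frames.frame_metrics(frame, admin),
                                 out / "metrics_quadtree.csv")
        for side in config.ugc_sides_m:
            ugc = frames.ugc_partition(smoothed, side)
            ugc.write_csv(out / f"frame_ugc_{int(side)}.csv")
            frames.write_metrics_csv(frames.frame_metrics(ugc, admin),
                                     out / f"metrics_ugc_{int(side)}.csv")
        done("frames", n_units=len(frame),
             frame_population=round(frame.total_population(), 3))

        # ---- allocate -----------------------------------------------
        stage_name = "allocate"
        specs = [
            design.StratumSpec(
                stratum_id=s.stratum_id,
                region_id=s.region_id,
                pop_type=s.pop_type,
                N_h=stratum_totals[s.stratum_id],
                S_h=_stratum_s_h(config, s.stratum_id),
                oversample_override=config.overrides.get(s.stratum_id),
            )
            for s in strata_polys
        ]
        pd.DataFrame(
            {
                "stratum_id": [s.stratum_id for s in specs],
                "region_id": [s.region_id for s in specs],
                "pop_type": [s.pop_type for s in specs],
                "N_h": [s.N_h for s in specs],
                "S_h": [s.S_h for s in specs],
                "override": [s.oversample_override for s in specs],
            }
        ).to_csv(out / "strata.csv", index=False)
        allocations = design.neyman_allocate(specs, config.n_total,
                                             config.min_per_stratum)
        design.write_allocation_csv(allocations, out / "allocation.csv")
        done("allocate", n_total=config.n_total,
             n_strata=len(allocations))

        # ---- sample -------------------------------------------------
        stage_name = "sample"
        by_stratum = {a.stratum_id: a.n_h for a in allocations}
        records: list[sampling.SelectionRecord] = []
        for s in strata_polys:
            k = by_stratum[s.stratum_id]
            if k == 0:
                continue
            sub_units = [u for u in frame if u.stratum_id == s.stratum_id]
            sub_frame = Frame(sub_units, method="quadtree")
            seed_h = sampling.derive_seed(config.master_seed, f"sample:{s.stratum_id}")
            main = sampling.pps_systematic(sub_frame, k, seed_h)
            repl = sampling.replacement_sample(sub_frame, k,
                                               config.replacement_rate, seed_h)
            if config.exclude_unit_ids:
                main = sampling.apply_exclusions(main, repl, config.exclude_unit_ids)
            records.extend(main)
            records.extend(repl)
        sampling.write_selections_csv(records, out / "selections.csv")
        done("sample", n_records=len(records),
             n_main=sum(1 for r in records if not r.is_replacement))

        # ---- weights ------------------------------------------------
        stage_name = "weights"
        pop_by_unit = {u.unit_id: u.population for u in frame}
        rows = []
        all_weights = []
        for r in records:
            if r.is_replacement:
                continue
            # expected_hits is k * pop_i / N_h, i.e. the printed P1; a
            # substituted record carries its original PSU's value.
            p1 = r.expected_hits
            pop_u = pop_by_unit.get(r.unit_id, 0.0)
            households = max(1, round(pop_u / config.mean_household_size))
            plan = weights.ssu_plan(households, r.multiplicity)
            hh_in_psu = max(households, plan.n_ssu)
            for j in range(plan.households_selected):
                rec = weights.household_weight(
                    p1, plan, hh_in_psu, household_id=f"{r.unit_id}:h{j}"
                )
                rows.append(
                    {
                        "household_id": rec.household_id,
                        "unit_id": r.unit_id,
                        "stratum_id": r.stratum_id,
                        "P1": rec.P1,
                        "P2": rec.P2,
                        "weight": rec.weight,
                        "certainty_capped": rec.certainty_capped,
                    }
                )
                all_weights.append(rec.weight)
        pd.DataFrame(rows).to_csv(out / "weights.csv", index=False)
        diag = weights.weight_diagnostics(all_weights)
        with open(out / "weight_diagnostics.json", "w") as fh:
            json.dump(
                {
                    "n": diag.n,
                    "ratio_max_min": diag.ratio_max_min,
                    "relvariance": diag.relvariance,
                    "deff_w": diag.deff_w,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        done("weights", n_households=diag.n, deff_w=round(diag.deff_w, 4))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage_name}' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
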