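import numpy as np
import pytest

from quadframe import PopulationGrid, QuadtreeSpec, quadtree_partition

from conftest import grid_from
from reference_quadtree import reference_partition


def units_as_tuples(frame, grid):
    """(row0, col0, n_rows, n_cols, pop, n_valid) per unit, for oracle comparison."""
    cs = grid.cell_size
    out = []
    for u in frame:
        c0 = round((u.extent.x_min - grid.origin_x) / cs)
        r0 = round((grid.origin_y - u.extent.y_max) / cs)
        nc = round(u.extent.width / cs)
        nr = round(u.extent.height / cs)
        out.append((r0, c0, nr, nc, u.population, u.n_cells_valid))
    return out


class TestSpecExamples:
    def test_forced_full_split_flags_unsplittable_unit(self):
        grid = grid_from(np.array([[10.0, 0.0], [0.0, 0.0]]))
        frame = quadtree_partition(grid, QuadtreeSpec(pop_max=5, side_max_m=3000))
        assert sorted(u.population for u in frame) == [0, 0, 0, 10]
        assert len(frame) == 4
        flagged = [u for u in frame if u.over_threshold]
        assert len(flagged) == 1 and flagged[0].population == 10
        assert all(u.n_cells_valid == 1 for u in frame)

    def test_no_split_needed(self):
        grid = grid_from(np.ones((2, 2)))
        frame = quadtree_partition(grid, QuadtreeSpec(pop_max=5, side_max_m=3000))
        assert len(frame) == 1
        assert frame.units[0].population == 4

    def test_even_split_into_four_quadrants(self):
        grid = grid_from(np.ones((8, 8)))
        frame = quadtree_partition(grid, QuadtreeSpec(pop_max=20, side_max_m=10_000))
        assert len(frame) == 4
        assert all(u.population == 16 for u in frame)
        assert all(u.side_m == 400.0 for u in frame)

    def test_area_rule_alone_forces_split(self):
        grid = grid_from(np.zeros((4, 4)))
        frame = quadtree_partition(grid, QuadtreeSpec(pop_max=3500, side_max_m=200))
        assert len(frame) == 4
        assert all(u.side_m == 200.0 for u in frame)
        assert all(u.population == 0 for u in frame)

    def test_empty_mask_gives_empty_frame(self):
        grid = PopulationGrid(np.zeros((4, 4)), 100.0, 0.0, 400.0,
                              mask=np.zeros((4, 4), dtype=bool))
        frame = quadtree_partition(grid, QuadtreeSpec())
        assert len(frame) == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_grids_match_reference(self, seed):
        rng = np.random.default_rng(seed)
        nr, nc = rng.integers(2, 64, 2)
        values = rng.uniform(0, 60, (nr, nc))
        mask = rng.random((nr, nc)) > 0.15
        grid = grid_from(np.where(mask, values, 0.0), mask=mask)
        spec = QuadtreeSpec(
            pop_max=float(rng.uniform(30, 400)),
            side_max_m=float(rng.choice([400, 900, 1600, 3000])),
        )
        frame = quadtree_partition(grid, spec)
        ref = reference_partition(
            grid.values, grid.mask, grid.cell_size, spec.pop_max, spec.side_max_m
        )
        assert units_as_tuples(frame, grid) == ref


class TestInvariants:
    def test_conservation_random_rasters(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            values = rng.uniform(0, 100, (33, 47))
            grid = grid_from(values)
            frame = quadtree_partition(grid, QuadtreeSpec(pop_max=500, side_max_m=1500))
            assert frame.total_population() == pytest.approx(values.sum(), rel=1e-9)

    def test_lowering_pop_max_never_decreases_unit_count(self):
        rng = np.random.default_rng(2)
        grid = grid_from(rng.uniform(0, 100, (32, 32)))
        counts = [
            len(quadtree_partition(grid, QuadtreeSpec(pop_max=p, side_max_m=100_000)))
            for p in [20_000, 5_000, 1_000, 300, 80]
        ]
        assert counts == sorted(counts)

    def test_deterministic_ids_and_order(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(0, 50, (20, 20))
        grid = grid_from(values)
        spec = QuadtreeSpec(pop_max=200, side_max_m=1000)
        f1 = quadtree_partition(grid, spec, stratum_id="s1")
        f2 = quadtree_partition(grid_from(values), spec, stratum_id="s1")
        assert [u.unit_id for u in f1] == [u.unit_id for u in f2]
        assert all(u.unit_id.startswith("s1:q") for u in f1)

    def test_constraints_when_no_cell_exceeds_pop_max(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 3000, (40, 40))  # every cell below 3500
        grid = grid_from(values)
        spec = QuadtreeSpec(pop_max=3500, side_max_m=3000)
        frame = quadtree_partition(grid, spec)
        assert all(u.population < 3500 for u in frame)
        assert all(u.side_m <= 3000 for u in frame)
        assert not any(u.over_threshold for u in frame)

    def test_units_do_not_overlap_and_cover_valid_cells(self):
        rng = np.random.default_rng(7)
        mask = rng.random((24, 24)) > 0.3
        values = np.where(mask, rng.uniform(0, 40, (24, 24)), 0.0)
        grid = grid_from(values, mask=mask)
        frame = quadtree_partition(grid, QuadtreeSpec(pop_max=100, side_max_m=800))
        covered = np.zeros_like(mask, dtype=int)
        cs = grid.cell_size
        for u in frame:
            c0 = round((u.extent.x_min - grid.origin_x) / cs)
            r0 = round((grid.origin_y - u.extent.y_max) / cs)
            r1 = min(r0 + round(u.extent.height / cs), 24)
            c1 = min(c0 + round(u.extent.width / cs), 24)
            covered[r0:r1, c0:c1] += 1
        assert covered.max() <= 1
        assert np.all(covered[mask] == 1)


def test_side_max_smaller_than_cell_rejected():
    grid = grid_from(np.ones((2, 2)))
    with pytest.raises(ValueError, match="side_max"):
        quadtree_partition(grid, QuadtreeSpec(pop_max=10, side_max_m=50))


def test_csv_and_geojson_outputs(tmp_path):
    import json

    import pandas as pd

    grid = grid_from(np.ones((4, 4)))
    frame = quadtree_partition(grid, QuadtreeSpec(pop_max=5, side_max_m=3000))
    df = pd.read_csv(frame.write_csv(tmp_path / "f.csv"))
    assert list(df.columns[:2]) == ["unit_id", "stratum_id"]
    assert len(df) == len(frame)
    doc = json.load(open(frame.write_geojson(tmp_path / "f.geojson")))
    assert len(doc["features"]) == len(frame)
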