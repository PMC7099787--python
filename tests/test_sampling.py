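import numpy as np
import pytest

from quadframe import pps_systematic, replacement_sample, select_household
from quadframe.grid_model import Extent
from quadframe.quadtree import Frame, FrameUnit
from quadframe.sampling import (
    _systematic_hits,
    apply_exclusions,
    derive_seed,
    selections_to_dataframe,
)


def frame_of(populations, stratum_id=""):
    units = [
        FrameUnit(
            unit_id=f"u{i}",
            extent=Extent(i * 100.0, 0.0, (i + 1) * 100.0, 100.0),
            side_m=100.0,
            population=float(p),
            stratum_id=stratum_id,
        )
        for i, p in enumerate(populations)
    ]
    return Frame(units)


class TestSystematicCore:
    def test_hand_walked_cumulation(self):
        # cum totals 10,20,30,40; interval 20; hits at 5 and 25 -> units 1 and 3
        hits = _systematic_hits(np.array([10.0, 10.0, 10.0, 10.0]), k=2, start=5.0)
        assert hits.tolist() == [1, 0, 1, 0]

    def test_start_outside_interval_rejected(self):
        with pytest.raises(ValueError):
            _systematic_hits(np.array([10.0, 10.0]), k=2, start=10.0)

    def test_large_unit_hit_multiple_times(self):
        hits = _systematic_hits(np.array([1.0, 98.0, 1.0]), k=10, start=0.5)
        assert hits[1] >= 9
        assert hits.sum() == 10


class TestPPS:
    def test_single_unit_absorbs_all_hits(self):
        records = pps_systematic(frame_of([50]), k=3, seed=0)
        assert len(records) == 1
        assert records[0].multiplicity == 3
        assert records[0].expected_hits == 3.0

    def test_multiplicities_sum_to_k_any_seed(self):
        frame = frame_of([3, 1, 7, 0.5, 20, 2])
        for seed in range(25):
            records = pps_systematic(frame, k=4, seed=seed)
            assert sum(r.multiplicity for r in records) == 4

    def test_zero_population_units_never_selected(self):
        frame = frame_of([5, 0, 5, 0])
        for seed in range(20):
            ids = {r.unit_id for r in pps_systematic(frame, k=3, seed=seed)}
            assert ids <= {"u0", "u2"}

    def test_empirical_frequency_matches_pps(self):
        """Over 10,000 seeded draws with sizes {1, 3}, k=1, selection
        frequencies approach {0.25, 0.75} (3 Monte-Carlo s.e.)."""
        frame = frame_of([1, 3])
        n_draws = 10_000
        count0 = sum(
            1
            for s in range(n_draws)
            if pps_systematic(frame, k=1, seed=s)[0].unit_id == "u0"
        )
        p_hat = count0 / n_draws
        se = (0.25 * 0.75 / n_draws) ** 0.5
        assert abs(p_hat - 0.25) <= 3 * se

    def test_deterministic_given_seed(self):
        frame = frame_of([3, 8, 1, 6])
        a = pps_systematic(frame, k=3, seed=42)
        b = pps_systematic(frame, k=3, seed=42)
        assert a == b

    def test_certainty_units_always_selected(self):
        # u1 holds more than the interval (total 40 / k 4 = 10) -> always in
        frame = frame_of([2, 25, 3, 10])
        for seed in range(30):
            ids = {r.unit_id for r in pps_systematic(frame, k=4, seed=seed)}
            assert "u1" in ids


class TestReplacement:
    @pytest.mark.parametrize("k, expected", [(10, 2), (3, 1), (5, 1)])
    def test_ceil_of_rate(self, k, expected):
        frame = frame_of(np.arange(1, 40, dtype=float))
        records = replacement_sample(frame, k=k, rate=0.2, seed=0)
        assert sum(r.multiplicity for r in records) == expected
        assert all(r.is_replacement for r in records)

    def test_independent_of_main_draw(self):
        """Across seeds 0..99 on a 100-unit frame the replacement draw
        differs from the main draw in nearly all cases."""
        rng = np.random.default_rng(123)
        frame = frame_of(rng.uniform(1, 10, 100))
        differs = 0
        for seed in range(100):
            main = {(r.unit_id, r.multiplicity) for r in pps_systematic(frame, 5, seed)}
            repl = {
                (r.unit_id, r.multiplicity)
                for r in replacement_sample(frame, 5, 0.2, seed)
            }
            if main != repl:
                differs += 1
        assert differs >= 95


class TestHouseholdSelection:
    def test_degenerate_single_choice(self):
        sel = select_household([1], [[1]], seed=0)
        assert sel[0].structure_index == 0 and sel[0].household_index == 0

    def test_one_selection_per_ssu(self):
        sel = select_household([2] * 12, [[3, 4]] * 12, seed=1)
        assert len(sel) == 12
        assert all(not s.needs_replacement for s in sel)

    def test_two_stage_probabilities(self):
        """2 structures of {1, 3} households: household probabilities are
        {1/2, 1/6, 1/6, 1/6} (checked by simulation, 3 s.e.)."""
        n = 20_000
        counts = {}
        for seed in range(n):
            s = select_household([2], [[1, 3]], seed=seed)[0]
            counts[(s.structure_index, s.household_index)] = (
                counts.get((s.structure_index, s.household_index), 0) + 1
            )
        expected = {(0, 0): 0.5, (1, 0): 1 / 6, (1, 1): 1 / 6, (1, 2): 1 / 6}
        for key, p in expected.items():
            se = (p * (1 - p) / n) ** 0.5
            assert abs(counts.get(key, 0) / n - p) <= 3 * se

    def test_empty_ssu_marked_for_replacement(self):
        sel = select_household([0, 1], [[], [2]], seed=0)
        assert sel[0].needs_replacement and sel[0].structure_index is None
        assert not sel[1].needs_replacement

    def test_structure_without_household_rejected(self):
        with pytest.raises(ValueError, match="household"):
            select_household([1], [[0]], seed=0)


class TestExclusionsAndIO:
    def test_substitute_inherits_original_probability(self):
        frame = frame_of([5, 5, 5, 5, 5])
        main = pps_systematic(frame, k=2, seed=3)
        repl = replacement_sample(frame, k=2, rate=0.5, seed=3)
        excluded = main[0].unit_id
        out = apply_exclusions(main, repl, [excluded])
        assert len(out) == len(main)
        sub = out[0]
        assert sub.unit_id != excluded
        assert sub.expected_hits == main[0].expected_hits
        assert not sub.is_replacement

    def test_selection_dataframe_columns(self):
        records = pps_systematic(frame_of([1, 2, 3]), k=2, seed=0)
        df = selections_to_dataframe(records)
        assert list(df.columns) == [
            "unit_id", "stratum_id", "multiplicity", "expected_hits",
            "is_replacement", "seed", "random_start",
        ]

    def test_derived_seeds_stable_and_bounded(self):
        s1 = derive_seed(42, "pps-main")
        assert s1 == derive_seed(42, "pps-main")
        assert s1 != derive_seed(42, "pps-replacement")
        assert 0 <= s1 < 2**31
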