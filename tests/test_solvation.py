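"""Rasterization, molarity counts, placement, and neutralization."""

import numpy as np
import pytest

from cgbuild.core import Bead, Box, SolventSpec
from cgbuild.solvation import (AVOGADRO_NM3, IonPlan, NeutralizationError,
                               SolvationError, neutralize, place_solvent,
                               rasterize, salt_counts, solvent_counts)


def water():
    return SolventSpec("W", [Bead("W", "W", (0, 0, 0), 0.0)], molarity=0.15)


def ion(name, q):
    return SolventSpec(name, [Bead(name, name, (0, 0, 0), q)],
                       role="positive-ion" if q > 0 else "negative-ion")


class TestRasterize:
    def test_empty_box_cell_count_and_volume(self):
        grid = rasterize(Box(10, 10, 10), [water()])
        assert grid.cell == 0.5
        assert grid.n_free == 8000
        assert grid.free_volume == pytest.approx(1000.0)

    def test_full_plane_hydrophobic_slab_subtracts_volume(self):
        grid = rasterize(Box(10, 10, 10), [water()],
                         membrane_slabs=[(4.0, 6.0, None)])
        assert grid.free_volume == pytest.approx(800.0)

    def test_single_bead_blocks_exactly_overlapping_cells(self):
        pos = np.array([[5.1, 5.1, 5.1]])
        r = 0.3
        grid = rasterize(Box(10, 10, 10), [water()], pos, r)
        blocked = np.argwhere(~grid.free)
        # brute force: a cell is blocked iff the sphere reaches into it
        expected = set()
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    lo = np.array([i, j, k]) * 0.5
                    nearest = np.clip(pos[0], lo, lo + 0.5)
                    if np.sum((pos[0] - nearest) ** 2) <= r * r:
                        expected.add((i, j, k))
        assert set(map(tuple, blocked)) == expected

    def test_cell_size_follows_largest_solvent(self):
        big = SolventSpec("DIO", [Bead("A", "DIO", (0, 0, 0)),
                                  Bead("B", "DIO", (0, 0, 0.8))], molarity=1.0)
        grid = rasterize(Box(8, 8, 8), [water(), big])
        assert grid.cell == pytest.approx(0.8)

    def test_fully_blocked_box_raises(self):
        with pytest.raises(SolvationError):
            rasterize(Box(1, 1, 1), [water()], membrane_slabs=[(0.0, 1.0, None)])


class TestSolventCounts:
    def test_molarity_to_count(self):
        got = solvent_counts(1000.0, [water()])
        assert got == {"W": 90}  # 0.15 * 0.6022 * 1000 = 90.33

    def test_even_mixture_beads_mode(self):
        a = SolventSpec("A", [Bead("A", "A", (0, 0, 0))], ratio=1.0)
        b = SolventSpec("B", [Bead("B", "B", (0, 0, 0))], ratio=1.0)
        got = solvent_counts(1000.0, [a, b], "beads",
                             total_molarity=100 / (AVOGADRO_NM3 * 1000.0))
        assert got == {"A": 50, "B": 50}

    def test_mapping_mode_weighs_by_mapping_factor(self):
        a = SolventSpec("A", [Bead("A", "A", (0, 0, 0))], ratio=1.0, mapping_factor=4)
        b = SolventSpec("B", [Bead("B", "B", (0, 0, 0))], ratio=1.0, mapping_factor=1)
        got = solvent_counts(1000.0, [a, b], "mapping",
                             total_molarity=100 / (AVOGADRO_NM3 * 1000.0))
        assert got == {"A": 80, "B": 20}

    def test_negative_molarity_rejected(self):
        with pytest.raises(ValueError):
            SolventSpec("W", [Bead("W", "W", (0, 0, 0))], molarity=-1.0)

    @pytest.mark.parametrize("molarity", [0.05, 0.15, 0.5, 1.0, 2.0])
    def test_molarity_recovery_within_one_molecule(self, molarity):
        spec = SolventSpec("S", [Bead("S", "S", (0, 0, 0))], molarity=molarity)
        v = 730.0
        n = solvent_counts(v, [spec])["S"]
        assert abs(n / (AVOGADRO_NM3 * v) - molarity) <= 1.0 / (AVOGADRO_NM3 * v)


class TestPlaceSolvent:
    def test_distinct_cells_and_volume_bookkeeping(self):
        grid = rasterize(Box(10, 10, 10), [water()])
        v0 = grid.free_volume
        placed = place_solvent(grid, {"W": 90}, seed=4)
        assert len(placed) == 90
        centers = {tuple(np.round(c, 6)) for _, c in placed}
        assert len(centers) == 90
        assert grid.free_volume == pytest.approx(v0 - 90 * grid.cell ** 3)

    def test_zero_counts_leave_grid_unchanged(self):
        grid = rasterize(Box(5, 5, 5), [water()])
        n0 = grid.n_free
        assert place_solvent(grid, {"W": 0}, seed=1) == []
        assert grid.n_free == n0

    def test_overfull_request_reports_shortfall(self):
        grid = rasterize(Box(1, 1, 1), [water()])
        with pytest.raises(SolvationError, match="short by 1"):
            place_solvent(grid, {"W": grid.n_free + 1}, seed=1)

    def test_no_placement_inside_hydrophobic_slab(self):
        grid = rasterize(Box(6, 6, 10), [water()],
                         membrane_slabs=[(4.0, 6.0, None)])
        placed = place_solvent(grid, {"W": 500}, seed=2)
        z = np.array([c[2] for _, c in placed])
        assert not np.any((z > 4.0) & (z < 6.0))


class TestNeutralize:
    def test_add_counterions_for_negative_system(self):
        plan = neutralize(-5, ion("NA", +1), ion("CL", -1), {}, "add")
        assert plan.add == {"NA": 5} and plan.remove == {}

    def test_zero_charge_is_identity(self):
        plan = neutralize(0, ion("NA", +1), ion("CL", -1), {}, "combined")
        assert plan.add == {} and plan.remove == {}

    def test_combined_puts_odd_remainder_on_addition(self):
        plan = neutralize(-5, ion("NA", +1), ion("CL", -1), {"CL": 10}, "combined")
        assert plan.add == {"NA": 3} and plan.remove == {"CL": 2}

    def test_remove_mode_fails_without_enough_co_ions(self):
        with pytest.raises(NeutralizationError, match="infeasible"):
            neutralize(-5, ion("NA", +1), ion("CL", -1), {"CL": 2}, "remove")

    @pytest.mark.parametrize("algorithm", ["add", "remove", "combined"])
    @pytest.mark.parametrize("q", range(-10, 11))
    def test_monovalent_closure_everywhere(self, algorithm, q):
        pos, neg = ion("NA", +1), ion("CL", -1)
        present = {"NA": 15, "CL": 15}
        plan = neutralize(q, pos, neg, present, algorithm)
        delta = plan.add.get("NA", 0) - plan.add.get("CL", 0) * 1 \
            - plan.remove.get("NA", 0) + plan.remove.get("CL", 0)
        # recompute the net charge after applying the plan
        net = q + plan.add.get("NA", 0) - plan.add.get("CL", 0) \
            - plan.remove.get("NA", 0) + plan.remove.get("CL", 0)
        assert net == 0

    @pytest.mark.parametrize("algorithm", ["add", "remove", "combined"])
    @pytest.mark.parametrize("q", range(-10, 11, 2))
    def test_divalent_closure_on_even_charges(self, algorithm, q):
        pos, neg = ion("CA", +2), ion("DA", -2)
        present = {"CA": 10, "DA": 10}
        plan = neutralize(q, pos, neg, present, algorithm)
        net = q + 2 * plan.add.get("CA", 0) - 2 * plan.add.get("DA", 0) \
            - 2 * plan.remove.get("CA", 0) + 2 * plan.remove.get("DA", 0)
        assert net == 0

    @pytest.mark.parametrize("q", range(-9, 0, 2))
    def test_mixed_valence_combined_closure_on_odd_charges(self, q):
        # divalent counterion, monovalent co-ion: removal fixes the parity
        pos, neg = ion("CA", +2), ion("CL", -1)
        plan = neutralize(q, pos, neg, {"CL": 10}, "combined")
        net = q + 2 * plan.add.get("CA", 0) + plan.remove.get("CL", 0)
        assert net == 0

    def test_odd_charge_with_divalent_adder_is_reported_infeasible(self):
        with pytest.raises(NeutralizationError):
            neutralize(-5, ion("CA", +2), ion("DA", -2), {}, "add")


class TestSaltCounts:
    def test_monovalent_pair_is_balanced(self):
        got = salt_counts(1000.0, 0.15, ion("NA", +1), ion("CL", -1))
        assert got == {"NA": 90, "CL": 90}

    def test_divalent_cation_doubles_anions(self):
        got = salt_counts(1000.0, 0.15, ion("CA", +2), ion("CL", -1))
        assert got == {"CA": 90, "CL": 180}
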