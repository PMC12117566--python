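"""End-to-end builds: determinism, charge closure, file consistency."""

import numpy as np
import pytest

from cgbuild.builder import BuildError, build_system, write_outputs
from cgbuild.core import (Box, FloodingRequest, LeafletSpec, MembraneSpec,
                          ProteinSpec, SolvationRequest, SolventSpec,
                          SystemSpec)
from cgbuild.gro import read_gro
from cgbuild.topology import parse_topology


def bilayer(comp, center=5.0, apl=0.6, holes=()):
    return MembraneSpec(leaflets=[
        LeafletSpec("upper", center, dict(comp), apl, holes=list(holes)),
        LeafletSpec("lower", center, dict(comp), apl, holes=list(holes))],
        center_z=center)


def solvated(fx, neutralize="add", salt=0.15):
    return SolvationRequest(
        solvents=[SolventSpec("W", fx.water.beads, molarity=6.0)],
        pos_ion=fx.pos_ion, neg_ion=fx.neg_ion,
        salt_molarity=salt, neutralize=neutralize)


class TestDeterminism:
    def test_same_spec_and_seed_give_byte_identical_gro(self, fx, tmp_path):
        outs = []
        for run in ("a", "b"):
            spec = SystemSpec(box=Box(6, 6, 10),
                              membranes=[bilayer({"LARG": 3, "SMAL": 1})],
                              solvation=solvated(fx),
                              out_gro=str(tmp_path / f"{run}.gro"), seed=11)
            res = build_system(spec, fx.lipids)
            write_outputs(res)
            outs.append((tmp_path / f"{run}.gro").read_bytes())
        assert outs[0] == outs[1]

    def test_different_seed_moves_solvent(self, fx, tmp_path):
        coords = []
        for seed in (1, 2):
            spec = SystemSpec(box=Box(5, 5, 5), solvation=solvated(fx, salt=0),
                              out_gro=str(tmp_path / f"{seed}.gro"), seed=seed)
            res = build_system(spec, fx.lipids)
            coords.append(res.all_coords())
        assert not np.array_equal(coords[0], coords[1])


class TestChargeClosure:
    @pytest.mark.parametrize("algorithm", ["add", "remove", "combined"])
    def test_anionic_membrane_ends_neutral(self, fx, tmp_path, algorithm):
        spec = SystemSpec(box=Box(6, 6, 10),
                          membranes=[bilayer({"LARG": 3, "ANIO": 1})],
                          solvation=solvated(fx, neutralize=algorithm, salt=1.0),
                          out_gro=str(tmp_path / "n.gro"), seed=3)
        res = build_system(spec, fx.lipids)
        assert int(round(res.total_charge)) == 0
        assert res.ion_plan is not None

    def test_remove_mode_without_salt_is_infeasible(self, fx, tmp_path):
        spec = SystemSpec(box=Box(6, 6, 10),
                          membranes=[bilayer({"ANIO": 1})],
                          solvation=solvated(fx, neutralize="remove", salt=0.0),
                          out_gro=str(tmp_path / "x.gro"), seed=3)
        with pytest.raises(Exception):
            build_system(spec, fx.lipids)


class TestFileConsistency:
    def test_ledger_bead_total_equals_gro_atom_count(self, fx, tmp_path):
        spec = SystemSpec(box=Box(6, 6, 10),
                          membranes=[bilayer({"LARG": 3, "SMAL": 1})],
                          solvation=solvated(fx),
                          flooding=[FloodingRequest(solute=fx.solute, count=5)],
                          out_gro=str(tmp_path / "s.gro"),
                          out_top=str(tmp_path / "s.top"), seed=5)
        res = build_system(spec, fx.lipids)
        write_outputs(res)
        _, records, _ = read_gro(str(tmp_path / "s.gro"))
        topo = parse_topology(str(tmp_path / "s.top"))
        total = 0
        for name, count in topo.ledger or []:
            total += count * topo.molecules[name].n_atoms
        # reparse the written [molecules] section independently
        lines = (tmp_path / "s.top").read_text().splitlines()
        idx = lines.index("[ molecules ]")
        total = sum(int(l.split()[1]) * topo.molecules[l.split()[0]].n_atoms
                    for l in lines[idx + 1:] if l.strip())
        assert total == len(records) == res.n_beads


class TestGeometry:
    def test_protein_footprint_reduces_lipid_count(self, fx, fx_files, tmp_path):
        base = SystemSpec(box=Box(8, 8, 10), membranes=[bilayer({"LARG": 1})],
                          out_gro=str(tmp_path / "a.gro"), seed=2)
        res0 = build_system(base, fx.lipids)
        withp = SystemSpec(box=Box(8, 8, 10), membranes=[bilayer({"LARG": 1})],
                           proteins=[ProteinSpec(fx_files.files["CYL.gro"],
                                                 translate=(4.0, 4.0, 3.5))],
                           out_gro=str(tmp_path / "b.gro"), seed=2)
        res1 = build_system(withp, fx.lipids)
        n0 = sum(p.n_max for p in res0.leaflet_plans)
        n1 = sum(p.n_max for p in res1.leaflet_plans)
        assert n1 < n0

    def test_membrane_pore_reduces_free_area(self, fx, tmp_path):
        pore = [(3.0, 3.0), (5.0, 3.0), (5.0, 5.0), (3.0, 5.0)]
        spec = SystemSpec(box=Box(8, 8, 10),
                          membranes=[bilayer({"LARG": 1}, holes=[pore])],
                          out_gro=str(tmp_path / "p.gro"), seed=2)
        res = build_system(spec, fx.lipids)
        assert res.leaflet_plans[0].a_free == pytest.approx(60.0)
        assert res.leaflet_plans[0].n_max == 100  # 60 / 0.6

    def test_stacked_membranes_build_in_z_order(self, fx, tmp_path):
        spec = SystemSpec(box=Box(6, 6, 20),
                          membranes=[bilayer({"LARG": 1}, center=14.0),
                                     bilayer({"LARG": 1}, center=6.0)],
                          out_gro=str(tmp_path / "st.gro"), seed=2)
        res = build_system(spec, fx.lipids)
        assert len(res.leaflet_plans) == 4
        # lipid z centroids form two separated bands
        z = res.all_coords()[:, 2]
        assert ((z < 10).sum() > 0) and ((z > 10).sum() > 0)

    def test_solvent_avoids_membrane_interior(self, fx, tmp_path):
        spec = SystemSpec(box=Box(6, 6, 12),
                          membranes=[bilayer({"LARG": 1}, center=6.0)],
                          solvation=solvated(fx, salt=0.0),
                          out_gro=str(tmp_path / "w.gro"), seed=4)
        res = build_system(spec, fx.lipids)
        wz = np.array([m.coords[0, 2] for m in res.molecules if m.name == "W"])
        assert len(wz) > 0
        assert not np.any(np.abs(wz - 6.0) < 1.0)  # tail region is dry

    def test_realized_apl_within_rounding_bound(self, fx, tmp_path):
        spec = SystemSpec(box=Box(7, 7, 10), membranes=[bilayer({"LARG": 1})],
                          out_gro=str(tmp_path / "apl.gro"), seed=6)
        res = build_system(spec, fx.lipids)
        for plan in res.leaflet_plans:
            n = sum(plan.counts.values())
            realized = plan.a_free / n
            assert abs(realized - 0.6) <= 0.6 * 0.5 / (n - 0.5)

    def test_fatal_diagnostics_abort(self, fx):
        with pytest.raises(BuildError, match="nothing to build"):
            build_system(SystemSpec(box=Box(5, 5, 5)), fx.lipids)
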