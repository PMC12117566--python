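"""Serial build pipeline: proteins → membranes → flooding → solvent →
ions → writers.

Every stage is a pure function of the spec and the master seed (each
stochastic stage derives its own child seed), so two runs of the same
spec produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon

from . import solvation as solv
from .allocation import allocate, round_half_away
from .core import (Bead, Box, LeafletSpec, LipidType, MembraneSpec,
                   SolventSpec, SystemSpec, build_order, derive_seed,
                   validate_spec)
from .gro import AtomRecord, read_gro, read_pdb, write_gro, write_pdb
from .packing import (LeafletRegion, assign_size_classes, initial_placement,
                      protein_footprint, realize_leaflet, relax)
from .topology import TopologySet, write_topology

__all__ = ["BuildError", "BuildResult", "build_system"]

#: default collision radius of an existing (protein/lipid) bead, nm
BEAD_RADIUS = 0.25


class BuildError(RuntimeError):
    """Fatal diagnostics or an infeasible stage."""


@dataclass
class PlacedMolecule:
    name: str            # moleculetype / ledger name
    resname: str
    bead_names: list[str]
    coords: np.ndarray   # (n_beads, 3)
    charge: float


@dataclass
class BuildResult:
    spec: SystemSpec
    molecules: list[PlacedMolecule] = field(default_factory=list)
    log: list[str] = field(default_factory=list)
    leaflet_plans: list = field(default_factory=list)
    ion_plan: Optional[solv.IonPlan] = None
    converged: bool = True

    @property
    def sequence(self) -> list[str]:
        return [m.name for m in self.molecules]

    @property
    def n_beads(self) -> int:
        return sum(len(m.bead_names) for m in self.molecules)

    @property
    def total_charge(self) -> float:
        return sum(m.charge for m in self.molecules)

    def all_coords(self) -> np.ndarray:
        if not self.molecules:
            return np.empty((0, 3))
        return np.vstack([m.coords for m in self.molecules])

    def to_records(self) -> list[AtomRecord]:
        records = []
        atomid = 0
        for resid, mol in enumerate(self.molecules, 1):
            for bname, (x, y, z) in zip(mol.bead_names, mol.coords):
                atomid += 1
                records.append(AtomRecord(resid=resid, resname=mol.resname,
                                          name=bname, atomid=atomid,
                                          x=float(x), y=float(y), z=float(z)))
        return records


def _load_protein(pspec, topology: Optional[TopologySet]) -> PlacedMolecule:
    reader = read_pdb if pspec.filename.lower().endswith(".pdb") else read_gro
    _, records, _ = reader(pspec.filename)
    coords = np.array([[r.x, r.y, r.z] for r in records], dtype=float)
    theta = math.radians(pspec.rotate_z_deg)
    if theta:
        c, s = math.cos(theta), math.sin(theta)
        com = coords.mean(axis=0)
        rel = coords - com
        coords = com + np.column_stack([c * rel[:, 0] - s * rel[:, 1],
                                        s * rel[:, 0] + c * rel[:, 1],
                                        rel[:, 2]])
    coords = coords + np.asarray(pspec.translate, dtype=float)
    name = pspec.moleculetype or records[0].resname
    charge = 0.0
    if topology is not None and name in topology.molecules:
        charge = topology.charge_of(name)
    return PlacedMolecule(name=name, resname=records[0].resname,
                          bead_names=[r.name for r in records],
                          coords=coords, charge=charge)


def _leaflet_geometry(spec: SystemSpec, lf: LeafletSpec,
                      protein_beads: np.ndarray, slab: tuple[float, float]
                      ) -> LeafletRegion:
    boundary = lf.boundary or [(0.0, 0.0), (spec.box.x, 0.0),
                               (spec.box.x, spec.box.y), (0.0, spec.box.y)]
    holes = [Polygon(h) for h in lf.holes]
    if len(protein_beads):
        fp = protein_footprint(protein_beads, BEAD_RADIUS, slab)
        if not fp.is_empty:
            holes.append(fp)
    return LeafletRegion(boundary, holes)


def _build_membrane(spec: SystemSpec, mem: MembraneSpec,
                    lipid_types: dict[str, LipidType],
                    protein_beads: np.ndarray, seed: int,
                    result: BuildResult) -> tuple[float, float, object]:
    """Build one membrane; returns its hydrophobic slab (z_lo, z_hi, footprint)."""
    tails_z: list[float] = []
    for idx, lf in enumerate(sorted(mem.leaflets, key=lambda l: 0 if l.side == "lower" else 1)):
        types = {n: lipid_types[n] for n in lf.composition}
        types = assign_size_classes(types) if len(types) > 1 else types
        height = max(max(abs(b.position[2]) for b in t.beads) for t in types.values())
        if lf.side == "upper":
            slab = (mem.center_z, mem.center_z + height)
            z_anchor = mem.center_z + height
        else:
            slab = (mem.center_z - height, mem.center_z)
            z_anchor = mem.center_z - height
        region = _leaflet_geometry(spec, lf, protein_beads, slab)
        if region.a_free <= 0:
            raise BuildError(f"leaflet {lf.side!r} of membrane at z={mem.center_z:g}: "
                             f"free area is zero")
        plan = allocate(lf.composition, region.a_free, lf.apl)
        result.leaflet_plans.append(plan)
        lseed = derive_seed(seed, f"leaflet:{mem.center_z}:{lf.side}")
        discs = initial_placement(plan, region, types, lseed)
        discs, conv = relax(discs, region, seed=lseed + 1)
        result.converged = result.converged and conv
        placed = realize_leaflet(discs, types, z_anchor, lf.side, lseed + 2)
        for name, beads, coords in placed:
            t = types[name]
            result.molecules.append(PlacedMolecule(
                name=name, resname=name, bead_names=[b.name for b in beads],
                coords=coords, charge=t.charge))
            for bi in t.tail_beads:
                tails_z.append(float(coords[bi, 2]))
        counts_str = ", ".join(f"{n}:{c}" for n, c in plan.counts.items())
        result.log.append(
            f"membrane z={mem.center_z:g} {lf.side} leaflet: A_free="
            f"{region.a_free:.2f} nm², n_max={plan.n_max} ({counts_str}), "
            f"relaxation {'converged' if conv else 'not converged'}")
    # hydrophobic slab: z-range of tail beads + 0.15 nm margin, over the
    # membrane footprint minus pores
    if tails_z:
        z_lo, z_hi = min(tails_z) - 0.15, max(tails_z) + 0.15
    else:
        z_lo = z_hi = mem.center_z
    lf0 = mem.leaflets[0]
    boundary = lf0.boundary or [(0.0, 0.0), (spec.box.x, 0.0),
                                (spec.box.x, spec.box.y), (0.0, spec.box.y)]
    footprint = Polygon(boundary)
    for h in lf0.holes:
        footprint = footprint.difference(Polygon(h))
    return (z_lo, z_hi, footprint)


def build_system(spec: SystemSpec, lipid_types: Optional[dict[str, LipidType]] = None,
                 topology: Optional[TopologySet] = None) -> BuildResult:
    """Run the full serial build for a validated spec."""
    diags = validate_spec(spec)
    fatal = [d for d in diags if d.fatal]
    if fatal:
        raise BuildError("; ".join(d.message for d in fatal))
    result = BuildResult(spec=spec)
    for d in diags:
        result.log.append(f"warning: {d.message}")
    lipid_types = lipid_types or {}
    stages = build_order(spec)
    result.log.append("stage order: " + " -> ".join(stages))

    # proteins
    protein_beads = np.empty((0, 3))
    if spec.proteins:
        for p in spec.proteins:
            mol = _load_protein(p, topology)
            result.molecules.append(mol)
            result.log.append(f"protein {mol.name}: {len(mol.bead_names)} beads, "
                              f"charge {mol.charge:+g}")
        protein_beads = result.all_coords()

    # membranes, ascending center z
    slabs = []
    for mem in sorted(spec.membranes, key=lambda m: m.center_z):
        missing = [n for lf in mem.leaflets for n in lf.composition
                   if n not in lipid_types]
        if missing:
            raise BuildError("unknown lipid types: " + ", ".join(sorted(set(missing))))
        slabs.append(_build_membrane(spec, mem, lipid_types, protein_beads,
                                     derive_seed(spec.seed, "membrane"), result))

    solvent_like: list[tuple[SolventSpec, int]] = []

    def place_into(grid, counts: dict[str, int], specs_by_name, seed):
        placements = solv.place_solvent(grid, counts, seed)
        for name, center in placements:
            s = specs_by_name[name]
            local = np.array([b.position for b in s.beads], dtype=float)
            local -= local.mean(axis=0)
            result.molecules.append(PlacedMolecule(
                name=name, resname=s.beads[0].resname,
                bead_names=[b.name for b in s.beads],
                coords=local + center, charge=s.charge))

    # flooding solutes
    if spec.flooding:
        fseed = derive_seed(spec.seed, "flooding")
        probe = [f.solute for f in spec.flooding]
        grid = solv.rasterize(spec.box, probe, result.all_coords(), BEAD_RADIUS, slabs)
        for f in spec.flooding:
            n = f.count if f.count is not None else round_half_away(
                f.molarity * solv.AVOGADRO_NM3 * grid.free_volume)
            place_into(grid, {f.solute.name: n}, {f.solute.name: f.solute}, fseed)
            result.log.append(f"flooding: {n} {f.solute.name}")

    # solvent
    grid = None
    if spec.solvation and spec.solvation.solvents:
        sv = spec.solvation
        grid = solv.rasterize(spec.box, sv.solvents, result.all_coords(),
                              BEAD_RADIUS, slabs)
        counts = solv.solvent_counts(grid.free_volume, sv.solvents, sv.ratio_mode)
        total = sum(counts.values())
        capacity = grid.n_free
        if total > capacity:
            # bulk saturation: the raster holds one molecule per cell, so a
            # request denser than the grid fills every available cell
            scale = capacity / total
            counts = {n: int(c * scale) for n, c in counts.items()}
            result.log.append(
                f"warning: solvent request ({total}) exceeds grid capacity "
                f"({capacity}); saturating the free volume")
        result.log.append(
            f"solvent: free volume {grid.free_volume:.1f} nm³, counts "
            + ", ".join(f"{n}:{c}" for n, c in counts.items()))
        place_into(grid, counts, {s.name: s for s in sv.solvents},
                   derive_seed(spec.seed, "solvent"))

    # salt + neutralization
    if spec.solvation and (spec.solvation.salt_molarity > 0 or
                           spec.solvation.pos_ion or spec.solvation.neg_ion):
        sv = spec.solvation
        if sv.pos_ion is None or sv.neg_ion is None:
            raise BuildError("ion stage requires both ion species")
        if grid is None:
            grid = solv.rasterize(spec.box, [sv.pos_ion, sv.neg_ion],
                                  result.all_coords(), BEAD_RADIUS, slabs)
        iseed = derive_seed(spec.seed, "ions")
        present = {sv.pos_ion.name: 0, sv.neg_ion.name: 0}
        if sv.salt_molarity > 0:
            salt = solv.salt_counts(grid.free_volume, sv.salt_molarity,
                                    sv.pos_ion, sv.neg_ion)
            place_into(grid, salt, {sv.pos_ion.name: sv.pos_ion,
                                    sv.neg_ion.name: sv.neg_ion}, iseed)
            present.update(salt)
            result.log.append("salt: " + ", ".join(f"{n}:{c}" for n, c in salt.items()))
        q = int(round(result.total_charge))
        plan = solv.neutralize(q, sv.pos_ion, sv.neg_ion, present, sv.neutralize)
        specs_by_name = {sv.pos_ion.name: sv.pos_ion, sv.neg_ion.name: sv.neg_ion}
        for name, n in plan.remove.items():
            removed = 0
            for i in range(len(result.molecules) - 1, -1, -1):
                if removed == n:
                    break
                if result.molecules[i].name == name:
                    del result.molecules[i]
                    removed += 1
            if removed < n:
                raise BuildError(f"cannot remove {n} {name}: only {removed} present")
        if plan.add:
            place_into(grid, plan.add, specs_by_name, iseed + 1)
        result.ion_plan = plan
        result.log.append(
            f"neutralization ({sv.neutralize}): charge {q:+d} -> add "
            f"{plan.add or '{}'}, remove {plan.remove or '{}'}; net "
            f"{int(round(result.total_charge)):+d}")
    return result


def write_outputs(result: BuildResult, topology: Optional[TopologySet] = None) -> list[str]:
    """Write the GRO (and optional PDB/top) files named by the spec."""
    spec = result.spec
    written = []
    records = result.to_records()
    box = (spec.box.x, spec.box.y, spec.box.z)
    write_gro(spec.out_gro, records, box)
    written.append(spec.out_gro)
    if spec.out_pdb:
        write_pdb(spec.out_pdb, records, box)
        written.append(spec.out_pdb)
    if spec.out_top:
        topo = topology or TopologySet()
        for mol in result.molecules:
            if mol.name not in topo.molecules:
                per_bead = mol.charge / len(mol.bead_names)
                topo.add_stub(mol.name, [per_bead] * len(mol.bead_names))
        write_topology(topo, spec.out_top, result.sequence)
        written.append(spec.out_top)
    return written
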