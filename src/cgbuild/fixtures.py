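"""Synthetic molecule templates and toy systems.

Everything the builder needs for testing is generated here
programmatically: generic lipid templates (one large two-tail, one small
one-tail, one anionic variant), a water bead, monovalent and divalent
ions, a two-bead flooding solute, toy proteins (a cylinder and an
hourglass bead stack), a fragment mini-library, and matching GROMACS
.itp files.  The geometry is idealized — beads on lattices and rings —
because these fixtures exercise algorithmic contracts (allocation,
packing, solvation, I/O), not force-field accuracy.  No downloads are
involved and the file set is deterministic per seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .core import Bead, LipidType, SolventSpec
from .gro import AtomRecord, write_gro
from .molecules import Fragment, Library, build_lipid, save_library

__all__ = ["FixtureSet", "fragment_library", "default_fixtures", "make_fixtures"]


def fragment_library() -> Library:
    """Minimal fragment set: two heads, one linker, two tail lengths."""
    lib = Library(name="mini-fragments", kind="fragment")
    lib.add("HPC", Fragment(
        name="HPC", kind="head",
        beads=[Bead("QH", "HPC", (0.0, 0.0, 0.0), 0.0)],
        anchors={"down": (0.0, 0.0, -0.3)}))
    lib.add("HNEG", Fragment(
        name="HNEG", kind="head",
        beads=[Bead("QN", "HNEG", (0.0, 0.0, 0.0), -1.0)],
        anchors={"down": (0.0, 0.0, -0.3)}))
    lib.add("GL2", Fragment(
        name="GL2", kind="linker",
        beads=[Bead("GL", "GL2", (0.0, 0.0, 0.0), 0.0)],
        anchors={"up": (0.0, 0.0, 0.0),
                 "tail1": (-0.25, 0.0, -0.3),
                 "tail2": (0.25, 0.0, -0.3)}))
    for n_beads, name in ((3, "C3"), (4, "C4")):
        beads = [Bead(f"C{i + 1}", name, (0.0, 0.0, -0.3 * (i + 1)), 0.0)
                 for i in range(n_beads)]
        lib.add(name, Fragment(name=name, kind="tail", beads=beads,
                               anchors={"up": (0.0, 0.0, 0.0)}))
    return lib


def _water() -> SolventSpec:
    return SolventSpec("W", [Bead("W", "W", (0.0, 0.0, 0.0), 0.0)], molarity=55.5)


def _ion(name: str, charge: float, role: str) -> SolventSpec:
    return SolventSpec(name, [Bead(name, name, (0.0, 0.0, 0.0), charge)], role=role)


def _solute() -> SolventSpec:
    return SolventSpec("FLD", [Bead("F1", "FLD", (0.0, 0.0, 0.0), 0.0),
                               Bead("F2", "FLD", (0.0, 0.0, 0.3), 0.0)],
                       role="solute")


def _cylinder_protein() -> tuple[np.ndarray, float]:
    """Bead stack of constant ring radius 0.5 nm spanning z∈[0, 3] nm."""
    pts = []
    for k, z in enumerate(np.arange(0.0, 3.01, 0.3)):
        for a in np.linspace(0, 2 * np.pi, 6, endpoint=False):
            pts.append([0.5 * np.cos(a), 0.5 * np.sin(a), z])
    return np.array(pts), 0.25


def _hourglass_protein() -> tuple[np.ndarray, float]:
    """Bead stack wide at both ends and narrow in the middle (z∈[0, 3])."""
    pts = []
    for z in np.arange(0.0, 3.01, 0.3):
        ring_r = 0.3 + 0.7 * abs(z - 1.5) / 1.5  # 1.0 at ends, 0.3 mid
        for a in np.linspace(0, 2 * np.pi, 6, endpoint=False):
            pts.append([ring_r * np.cos(a), ring_r * np.sin(a), z])
    return np.array(pts), 0.25


@dataclass
class FixtureSet:
    """All synthetic templates, plus file paths once written to disk."""

    lipids: dict[str, LipidType]
    water: SolventSpec
    pos_ion: SolventSpec
    neg_ion: SolventSpec
    divalent_ion: SolventSpec
    solute: SolventSpec
    proteins: dict[str, tuple[np.ndarray, float]]
    fragments: Library
    files: dict[str, str] = field(default_factory=dict)

    @property
    def solvent_specs(self) -> list[SolventSpec]:
        return [self.water, self.pos_ion, self.neg_ion, self.solute]


def default_fixtures() -> FixtureSet:
    """Build the in-memory fixture set (no files written)."""
    frags = fragment_library()
    larg = build_lipid("HPC", "GL2", ["C4", "C4"], [frags], name="LARG")
    smal = build_lipid("HPC", "GL2", ["C3"], [frags], name="SMAL")
    anio = build_lipid("HNEG", "GL2", ["C4", "C4"], [frags], name="ANIO")
    smal.size_class = "small"
    lipids = {"LARG": larg, "SMAL": smal, "ANIO": anio}
    return FixtureSet(
        lipids=lipids,
        water=_water(),
        pos_ion=_ion("NA", +1.0, "positive-ion"),
        neg_ion=_ion("CL", -1.0, "negative-ion"),
        divalent_ion=_ion("CA", +2.0, "positive-ion"),
        solute=_solute(),
        proteins={"CYL": _cylinder_protein(), "HGL": _hourglass_protein()},
        fragments=frags,
    )


def _write_itp(path: str, entries: dict[str, list[tuple[str, str, float]]]) -> None:
    """entries: moleculetype -> [(atom name, resname, charge), ...]"""
    with open(path, "w") as fh:
        for mol, atoms in entries.items():
            fh.write(f"[ moleculetype ]\n{mol}    1\n\n[ atoms ]\n")
            for i, (aname, resname, q) in enumerate(atoms, 1):
                fh.write(f"{i:5d}  P1  1  {resname:<5s} {aname:<5s} {i:5d} {q:8.3f}\n")
            fh.write("\n")


def _molecule_gro(path: str, name: str, beads: list[Bead]) -> None:
    records = [AtomRecord(1, b.resname, b.name, i, *b.position)
               for i, b in enumerate(beads, 1)]
    pos = np.array([b.position for b in beads])
    span = tuple(pos.max(axis=0) - pos.min(axis=0) + 2.0)
    write_gro(path, records, span, title=f"fixture {name}")


def make_fixtures(seed: int, outdir: str) -> FixtureSet:
    """Write the fixture file set (GRO structures, itp tree, fragment
    library YAML) under ``outdir``; deterministic per seed."""
    rng = np.random.default_rng(seed)
    fx = default_fixtures()
    os.makedirs(outdir, exist_ok=True)

    # structures
    for name, lipid in fx.lipids.items():
        p = os.path.join(outdir, f"{name}.gro")
        _molecule_gro(p, name, lipid.beads)
        fx.files[f"{name}.gro"] = p
    for spec in (fx.water, fx.pos_ion, fx.neg_ion, fx.divalent_ion, fx.solute):
        p = os.path.join(outdir, f"{spec.name}.gro")
        _molecule_gro(p, spec.name, spec.beads)
        fx.files[f"{spec.name}.gro"] = p
    for name, (pts, radius) in fx.proteins.items():
        # tiny seeded jitter so the toy proteins are not perfectly
        # symmetric (exercises footprint polygonization)
        jitter = rng.normal(0.0, 0.005, size=pts.shape)
        records = [AtomRecord(1 + i // 6, name, "BB", i + 1, *(pt + j))
                   for i, (pt, j) in enumerate(zip(pts, jitter))]
        p = os.path.join(outdir, f"{name}.gro")
        write_gro(p, records, (4.0, 4.0, 4.0), title=f"fixture protein {name}")
        fx.files[f"{name}.gro"] = p

    # topology tree: topol.top -> molecules.itp -> ions.itp (3 levels)
    ions_itp = os.path.join(outdir, "ions.itp")
    _write_itp(ions_itp, {
        "NA": [("NA", "NA", 1.0)],
        "CL": [("CL", "CL", -1.0)],
        "CA": [("CA", "CA", 2.0)],
    })
    mols_itp = os.path.join(outdir, "molecules.itp")
    with open(mols_itp, "w") as fh:
        fh.write('#include "ions.itp"\n\n')
    lipid_entries = {
        name: [(b.name, b.resname, b.charge) for b in lipid.beads]
        for name, lipid in fx.lipids.items()
    }
    lipid_entries["W"] = [("W", "W", 0.0)]
    lipid_entries["FLD"] = [("F1", "FLD", 0.0), ("F2", "FLD", 0.0)]
    for name, (pts, _) in fx.proteins.items():
        lipid_entries[name] = [("BB", name, 0.0)] * len(pts)
    _append_itp(mols_itp, lipid_entries)
    top = os.path.join(outdir, "topol.top")
    with open(top, "w") as fh:
        fh.write('; fixture topology\n#include "molecules.itp"\n')
    fx.files.update({"ions.itp": ions_itp, "molecules.itp": mols_itp,
                     "topol.top": top})

    frag_path = os.path.join(outdir, "fragments.yaml")
    save_library(fx.fragments, frag_path)
    fx.files["fragments.yaml"] = frag_path
    return fx


def _append_itp(path: str, entries: dict[str, list[tuple[str, str, float]]]) -> None:
    with open(path, "a") as fh:
        for mol, atoms in entries.items():
            fh.write(f"[ moleculetype ]\n{mol}    1\n\n[ atoms ]\n")
            for i, (aname, resname, q) in enumerate(atoms, 1):
                fh.write(f"{i:5d}  P1  1  {resname:<5s} {aname:<5s} {i:5d} {q:8.3f}\n")
            fh.write("\n")
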