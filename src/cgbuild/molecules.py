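"""Parameter libraries, fragment-based lipid assembly, import, and
structure-only output.

Lipids can be assembled from head / linker / tail fragments.  Fragment
geometry follows one convention: the head-side anchor of every fragment
sits at its local origin and the fragment extends along −z (tails point
downward for an upper leaflet, so building the lower leaflet is a plain
z-negation).  Assembly is translation-only — each fragment is shifted so
its head-side anchor lands on the partner's anchor point — which keeps
all intra-fragment distances exactly and makes the molecule charge the
exact sum of the fragment charges.

Libraries are plain YAML documents (name, kind, entries); several
libraries of the same kind may coexist and are searched in the
user-declared priority order, so a development library can shadow a
released one molecule by molecule.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .core import Bead, LipidType
from .gro import AtomRecord, read_gro, read_pdb, write_gro

__all__ = [
    "Fragment",
    "Molecule",
    "Library",
    "LibraryError",
    "AssemblyError",
    "load_library",
    "build_lipid",
    "packing_radius",
    "import_molecule",
    "query_library",
    "craft",
]


class LibraryError(KeyError):
    """Molecule or fragment not resolvable through the library search path."""


class AssemblyError(RuntimeError):
    """Fragment combination violates the assembly rules."""


@dataclass
class Fragment:
    """A lipid building block with named attachment points.

    ``anchors`` maps anchor names to local positions (nm).  A head needs
    at least one downward anchor ("down"); a linker needs the head-side
    anchor ("up") plus one or more tail-side anchors ("tail1", ...); a
    tail has exactly the head-side anchor ("up").
    """

    name: str
    kind: str  # head | linker | tail
    beads: list[Bead]
    anchors: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind == "head" and not any(a.startswith("down") for a in self.anchors):
            raise ValueError(f"head fragment {self.name!r} needs a 'down' anchor")
        if self.kind == "linker":
            if "up" not in self.anchors:
                raise ValueError(f"linker fragment {self.name!r} needs an 'up' anchor")
            if not self.tail_anchors:
                raise ValueError(f"linker fragment {self.name!r} needs tail anchors")
        if self.kind == "tail" and "up" not in self.anchors:
            raise ValueError(f"tail fragment {self.name!r} needs an 'up' anchor")

    @property
    def tail_anchors(self) -> list[str]:
        return sorted(a for a in self.anchors if a.startswith("tail"))

    @property
    def charge(self) -> float:
        return sum(b.charge for b in self.beads)


@dataclass
class Molecule:
    """A ready molecule (imported or assembled)."""

    name: str
    beads: list[Bead]

    @property
    def charge(self) -> float:
        return sum(b.charge for b in self.beads)


@dataclass
class Library:
    """A named collection of molecules or fragments of one kind."""

    name: str
    kind: str  # lipid | solvent | ion | fragment | protein | solute
    entries: dict[str, object] = field(default_factory=dict)

    def add(self, name: str, entry: object) -> None:
        self.entries[name] = entry


def resolve(name: str, libraries: Sequence[Library],
            kind: Optional[str] = None) -> object:
    """Look a name up across libraries in priority order (first wins)."""
    searched = []
    for lib in libraries:
        if kind is not None and lib.kind != kind:
            continue
        searched.append(lib.name)
        if name in lib.entries:
            return lib.entries[name]
    raise LibraryError(
        f"{name!r} not found; searched libraries: {', '.join(searched) or '(none)'}")


def load_library(path: str) -> Library:
    """Load a library from its YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    lib = Library(name=doc["name"], kind=doc["kind"])
    for name, e in (doc.get("entries") or {}).items():
        beads = [Bead(b[0], b[1], tuple(float(v) for v in b[2]),
                      float(b[3]) if len(b) > 3 else 0.0)
                 for b in e["beads"]]
        if lib.kind == "fragment":
            anchors = {a: tuple(float(v) for v in p)
                       for a, p in (e.get("anchors") or {}).items()}
            lib.add(name, Fragment(name=name, kind=e["kind"], beads=beads,
                                   anchors=anchors))
        else:
            lib.add(name, Molecule(name=name, beads=beads))
    return lib


def save_library(lib: Library, path: str) -> None:
    doc = {"name": lib.name, "kind": lib.kind, "entries": {}}
    for name, e in lib.entries.items():
        entry = {"beads": [[b.name, b.resname, list(b.position), b.charge]
                           for b in e.beads]}
        if isinstance(e, Fragment):
            entry["kind"] = e.kind
            entry["anchors"] = {a: list(p) for a, p in e.anchors.items()}
        doc["entries"][name] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def packing_radius(beads: Sequence[Bead], padding: float = 0.1) -> float:
    """Packing radius of a template: half the maximal xy bead-pair
    distance plus a contact padding (default 0.1 nm)."""
    xy = np.array([b.position[:2] for b in beads], dtype=float)
    if len(xy) == 1:
        return padding
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    return float(d.max()) / 2.0 + padding


def _translated(frag: Fragment, shift: np.ndarray, resname: str) -> list[Bead]:
    return [Bead(b.name, resname, tuple(np.asarray(b.position) + shift), b.charge)
            for b in frag.beads]


def build_lipid(head: str, linker: str, tails: Sequence[str],
                libraries: Sequence[Library], name: Optional[str] = None
                ) -> LipidType:
    """Assemble a lipid from named fragments.

    Beads are concatenated head → linker → tails, each fragment
    translated so its head-side anchor coincides with the partner's
    anchor point.  The tail count must not exceed the linker's tail-side
    anchors.
    """
    h: Fragment = resolve(head, libraries, kind="fragment")
    ln: Fragment = resolve(linker, libraries, kind="fragment")
    ts: list[Fragment] = [resolve(t, libraries, kind="fragment") for t in tails]
    for frag, want in ((h, "head"), (ln, "linker")):
        if frag.kind != want:
            raise AssemblyError(f"{frag.name!r} is a {frag.kind}, expected {want}")
    for t in ts:
        if t.kind != "tail":
            raise AssemblyError(f"{t.name!r} is a {t.kind}, expected tail")
    tail_slots = ln.tail_anchors
    if len(ts) > len(tail_slots):
        raise AssemblyError(
            f"linker {ln.name!r} provides {len(tail_slots)} tail anchors but "
            f"{len(ts)} tails were requested")

    resname = name or f"{head[:2]}{linker[:1]}{len(tails)}T"
    down = next(a for a in sorted(h.anchors) if a.startswith("down"))
    beads: list[Bead] = _translated(h, np.zeros(3), resname)
    link_shift = np.asarray(h.anchors[down]) - np.asarray(ln.anchors["up"])
    beads += _translated(ln, link_shift, resname)
    tail_indices: list[int] = []
    for t, slot in zip(ts, tail_slots):
        t_shift = link_shift + np.asarray(ln.anchors[slot]) - np.asarray(t.anchors["up"])
        start = len(beads)
        beads += _translated(t, t_shift, resname)
        tail_indices.extend(range(start, len(beads)))
    return LipidType(name=resname, beads=beads, radius=packing_radius(beads),
                     tail_beads=tuple(tail_indices))


def import_molecule(structure_file: str, libraries: Sequence[Library],
                    library: Library, topology=None,
                    moleculetype: Optional[str] = None,
                    name: Optional[str] = None) -> Molecule:
    """Import a molecule from a GRO/PDB file into a library.

    With a topology set and moleculetype name, per-bead charges are taken
    from the parsed ``[atoms]`` block (bead counts must match); without a
    topology all charges default to zero with a warning.
    """
    import warnings

    reader = read_pdb if structure_file.lower().endswith(".pdb") else read_gro
    _, records, _ = reader(structure_file)
    if not records:
        raise ValueError(f"{structure_file}: no atoms found")
    charges = [0.0] * len(records)
    if topology is not None and moleculetype is not None:
        entry = topology.molecules.get(moleculetype)
        if entry is None:
            raise LibraryError(f"moleculetype {moleculetype!r} not in topology")
        if entry.n_atoms != len(records):
            raise ValueError(
                f"bead-count mismatch for {moleculetype!r}: structure has "
                f"{len(records)} beads, topology has {entry.n_atoms} atoms")
        charges = list(entry.charges)
    else:
        warnings.warn(f"{structure_file}: imported without topology; "
                      f"all charges set to 0")
    mol_name = name or moleculetype or records[0].resname
    beads = [Bead(r.name, r.resname, (r.x, r.y, r.z), q)
             for r, q in zip(records, charges)]
    mol = Molecule(name=mol_name, beads=beads)
    library.add(mol_name, mol)
    return mol


def query_library(pattern: str, libraries: Sequence[Library]) -> list[dict]:
    """List entries matching a glob pattern across all libraries.

    Entries come out in library priority order; a name shadowed by a
    higher-priority library is still listed, with its priority rank.
    """
    out = []
    for rank, lib in enumerate(libraries):
        for name in sorted(lib.entries):
            if fnmatch.fnmatch(name, pattern):
                e = lib.entries[name]
                out.append({
                    "name": name,
                    "library": lib.name,
                    "priority": rank,
                    "kind": e.kind if isinstance(e, Fragment) else lib.kind,
                    "n_beads": len(e.beads),
                    "charge": e.charge,
                })
    return out


def craft(request, libraries: Sequence[Library], out_path: str) -> int:
    """Write a single molecule's structure file, without a system build.

    ``request`` is either a molecule name to resolve, or a
    ``(head, linker, [tails...])`` triple to assemble.  Returns the bead
    count written.
    """
    if isinstance(request, str):
        mol = resolve(request, libraries)
    else:
        head, linker, tails = request
        mol = build_lipid(head, linker, tails, libraries)
    records = [
        AtomRecord(resid=1, resname=b.resname, name=b.name, atomid=i,
                   x=b.position[0], y=b.position[1], z=b.position[2])
        for i, b in enumerate(mol.beads, 1)
    ]
    pos = np.array([b.position for b in mol.beads])
    span = pos.max(axis=0) - pos.min(axis=0) + 2.0
    write_gro(out_path, records, tuple(span), title=f"crafted {mol.name}")
    return len(records)
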