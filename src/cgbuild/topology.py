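"""GROMACS topology handling: recursive include parsing, charge
extraction, and output-topology writing.

Only the directives needed for system building are interpreted —
``#include``, ``[ moleculetype ]``, ``[ atoms ]``, ``[ system ]`` and
``[ molecules ]``.  Charges come from the charge column of the atoms
block; everything else is passed through verbatim when writing the
output topology, whose ``[ molecules ]`` ledger lists the built
composition in build order with consecutive identical molecules merged
into one counted line.  ``#ifdef``/``#endif`` blocks are passed through
unevaluated; atoms inside them are ignored for charge purposes (with a
warning), since preprocessor semantics belong to GROMACS.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field

__all__ = ["TopologySet", "TopologyError", "parse_topology", "write_topology"]


class TopologyError(RuntimeError):
    """Parse or consistency failure in a topology tree."""


@dataclass
class MoleculeTopology:
    name: str
    charges: list[float]
    source: str  # file the [moleculetype] came from

    @property
    def charge(self) -> float:
        return sum(self.charges)

    @property
    def n_atoms(self) -> int:
        return len(self.charges)


@dataclass
class TopologySet:
    """Charges per moleculetype plus the output [molecules] ledger."""

    molecules: dict[str, MoleculeTopology] = field(default_factory=dict)
    root_file: str | None = None
    include_lines: list[str] = field(default_factory=list)
    ledger: list[tuple[str, int]] = field(default_factory=list)

    def charge_of(self, name: str) -> float:
        return self.molecules[name].charge

    def add_stub(self, name: str, charges: list[float]) -> None:
        """Register a generated moleculetype (e.g. a fixture template)."""
        self.molecules[name] = MoleculeTopology(name, list(charges), "<generated>")


_SECTION_RE = re.compile(r"^\s*\[\s*(\S+)\s*\]")
_INCLUDE_RE = re.compile(r'^\s*#include\s+"([^"]+)"')


def _strip_comment(line: str) -> str:
    return line.split(";", 1)[0]


def _parse_file(path: str, topo: TopologySet, chain: list[str]) -> None:
    if not os.path.exists(path):
        raise TopologyError(
            "missing include target: " + " -> ".join(chain + [path]))
    section = None
    current: MoleculeTopology | None = None
    ifdef_depth = 0
    warned_ifdef = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            m = _INCLUDE_RE.match(raw)
            if m:
                target = os.path.join(os.path.dirname(path), m.group(1))
                _parse_file(os.path.normpath(target), topo, chain + [path])
                continue
            stripped = raw.strip()
            if stripped.startswith(("#ifdef", "#ifndef")):
                ifdef_depth += 1
                continue
            if stripped.startswith("#endif"):
                ifdef_depth = max(0, ifdef_depth - 1)
                continue
            if stripped.startswith("#else"):
                continue
            if ifdef_depth > 0:
                if not warned_ifdef and _SECTION_RE.match(raw):
                    warnings.warn(f"{path}: content inside #ifdef is passed through "
                                  f"unevaluated; charges there are ignored")
                    warned_ifdef = True
                continue
            line = _strip_comment(raw).strip()
            if not line:
                continue
            m = _SECTION_RE.match(line)
            if m:
                section = m.group(1).lower()
                if section == "moleculetype":
                    current = None
                continue
            if section == "moleculetype":
                name = line.split()[0]
                if name in topo.molecules:
                    raise TopologyError(
                        f"duplicate [moleculetype] definition of {name!r} "
                        f"(first in {topo.molecules[name].source}, again in {path})")
                current = MoleculeTopology(name, [], path)
                topo.molecules[name] = current
            elif section == "atoms" and current is not None:
                fields = line.split()
                # id type resnr residue atom cgnr charge [mass]
                if len(fields) < 7:
                    raise TopologyError(
                        f"malformed atoms line at {path}:{lineno}: {raw.rstrip()!r}")
                try:
                    charge = float(fields[6])
                except ValueError as exc:
                    raise TopologyError(
                        f"malformed atoms line at {path}:{lineno}: {exc}") from exc
                current.charges.append(charge)


def parse_topology(root: str) -> TopologySet:
    """Parse a .top/.itp tree, resolving ``#include`` depth-first.

    Include targets are resolved relative to the including file.  All
    ``[moleculetype]``/``[atoms]`` blocks across the tree are collected;
    duplicate moleculetype names raise :class:`TopologyError`.
    """
    topo = TopologySet(root_file=root)
    if not os.path.exists(root):
        raise TopologyError(f"topology file not found: {root}")
    with open(root) as fh:
        for raw in fh:
            if _INCLUDE_RE.match(raw):
                topo.include_lines.append(raw.rstrip("\n"))
    _parse_file(root, topo, [])
    return topo


def merge_runs(sequence: list[str]) -> list[tuple[str, int]]:
    """Run-length encode the build-order molecule sequence."""
    out: list[tuple[str, int]] = []
    for name in sequence:
        if out and out[-1][0] == name:
            out[-1] = (name, out[-1][1] + 1)
        else:
            out.append((name, 1))
    return out


def write_topology(topo: TopologySet, path: str, built: list[str],
                   system_name: str = "built system",
                   require_entries: bool = True) -> None:
    """Write the output .top for a built system.

    ``built`` is the molecule-name sequence in build order; consecutive
    identical names are merged into one counted ``[ molecules ]`` line.
    Original ``#include`` lines are preserved.  With ``require_entries``
    every built molecule must have a topology entry (parsed or stub).
    """
    ledger = merge_runs(built)
    if require_entries:
        missing = sorted({n for n, _ in ledger} - set(topo.molecules))
        if missing:
            raise TopologyError(
                "built molecules lack topology entries: " + ", ".join(missing))
    topo.ledger = ledger
    with open(path, "w") as fh:
        fh.write("; topology written by cgbuild\n")
        for line in topo.include_lines:
            fh.write(line + "\n")
        for mol in topo.molecules.values():
            # generated stubs and root-inline definitions are re-emitted;
            # everything defined in an include file travels with it
            if mol.source == "<generated>" or mol.source == topo.root_file:
                fh.write(f"\n[ moleculetype ]\n{mol.name}    1\n[ atoms ]\n")
                for i, q in enumerate(mol.charges, 1):
                    fh.write(f"{i:5d}  P1  1  {mol.name:<5s} B{i:<3d} {i:5d} {q:8.3f}\n")
        fh.write(f"\n[ system ]\n{system_name}\n\n[ molecules ]\n")
        for name, count in ledger:
            fh.write(f"{name:<15s} {count}\n")
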