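"""Fixed-width GRO coordinate I/O (and a secondary PDB writer).

The GRO dialect written here is the GROMACS standard: a title line, an
atom count, one fixed-width line per atom —

    residue number %5d, residue name %-5s, atom name %5s,
    atom number %5d, x/y/z %8.3f (nm)

— and a box-vector line.  Residue and atom numbers wrap at 100000, as
the five-column fields require.  A write→read round trip preserves all
names and positions to three decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["AtomRecord", "read_gro", "write_gro", "read_pdb", "write_pdb"]


@dataclass
class AtomRecord:
    """One atom/bead line of a coordinate file (positions in nm)."""

    resid: int
    resname: str
    name: str
    atomid: int
    x: float
    y: float
    z: float

    @property
    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


def read_gro(path: str) -> tuple[str, list[AtomRecord], tuple[float, float, float]]:
    """Read a GRO file: returns (title, records, box lengths in nm)."""
    with open(path) as fh:
        title = fh.readline().rstrip("\n")
        n = int(fh.readline().split()[0])
        records = []
        for _ in range(n):
            line = fh.readline()
            records.append(AtomRecord(
                resid=int(line[0:5]),
                resname=line[5:10].strip(),
                name=line[10:15].strip(),
                atomid=int(line[15:20]),
                x=float(line[20:28]),
                y=float(line[28:36]),
                z=float(line[36:44]),
            ))
        box_fields = fh.readline().split()
    box = tuple(float(v) for v in box_fields[:3])
    return title, records, box


def write_gro(path: str, records: Sequence[AtomRecord],
              box: tuple[float, float, float], title: str = "built system") -> None:
    """Write records in the fixed-width GRO dialect.

    Raises ``ValueError`` on any non-finite coordinate, naming the bead.
    """
    for r in records:
        if not np.all(np.isfinite([r.x, r.y, r.z])):
            raise ValueError(f"non-finite coordinate on bead {r.name!r} "
                             f"(residue {r.resname!r} {r.resid})")
    with open(path, "w") as fh:
        fh.write(f"{title}\n{len(records)}\n")
        for r in records:
            fh.write("%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n" % (
                r.resid % 100000, r.resname[:5], r.name[:5], r.atomid % 100000,
                r.x, r.y, r.z))
        fh.write("%10.5f%10.5f%10.5f\n" % box)


def write_pdb(path: str, records: Sequence[AtomRecord],
              box: tuple[float, float, float], title: str = "built system") -> None:
    """Secondary PDB writer (coordinates converted nm → Å)."""
    for r in records:
        if not np.all(np.isfinite([r.x, r.y, r.z])):
            raise ValueError(f"non-finite coordinate on bead {r.name!r} "
                             f"(residue {r.resname!r} {r.resid})")
    with open(path, "w") as fh:
        fh.write(f"TITLE     {title}\n")
        fh.write("CRYST1%9.3f%9.3f%9.3f  90.00  90.00  90.00 P 1           1\n"
                 % (box[0] * 10, box[1] * 10, box[2] * 10))
        for r in records:
            fh.write("ATOM  %5d %-4s %-4s%5d    %8.3f%8.3f%8.3f  1.00  0.00\n" % (
                r.atomid % 100000, r.name[:4], r.resname[:4], r.resid % 10000,
                r.x * 10, r.y * 10, r.z * 10))
        fh.write("END\n")


def read_pdb(path: str) -> tuple[str, list[AtomRecord], tuple[float, float, float]]:
    """Minimal PDB reader (ATOM/HETATM records; Å converted to nm)."""
    title = ""
    records: list[AtomRecord] = []
    box = (0.0, 0.0, 0.0)
    with open(path) as fh:
        for line in fh:
            if line.startswith("TITLE"):
                title = line[10:].strip()
            elif line.startswith("CRYST1"):
                box = (float(line[6:15]) / 10, float(line[15:24]) / 10,
                       float(line[24:33]) / 10)
            elif line.startswith(("ATOM", "HETATM")):
                records.append(AtomRecord(
                    resid=int(line[22:26]),
                    resname=line[17:21].strip(),
                    name=line[12:16].strip(),
                    atomid=int(line[6:11]),
                    x=float(line[30:38]) / 10,
                    y=float(line[38:46]) / 10,
                    z=float(line[46:54]) / 10,
                ))
    return title, records, box
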