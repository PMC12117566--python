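"""Solvation: box rasterization, molarity-based insertion, neutralization.

The box is rasterized into cubic cells whose edge equals the length of
the largest solvent molecule (floor 0.5 nm, roughly one CG water bead).
Cells already claimed by system beads, or lying inside a membrane's
hydrophobic slab, are unavailable; the solvent count follows from the
molarity applied to the *free* volume only,

    N = [M * N_A * V_free],   N_A = 0.6022140857 nm^-3 M^-1,

so the realized concentration tracks the request to within one molecule
whatever the membrane/protein content of the box.  Whole molecules are
counted, not beads.

Mixed solvents share one total molarity and are split by their ratio
weights, interpreted either per CG molecule ("beads" mode) or weighted
by the atom-to-bead mapping factor of each species ("mapping" mode,
matching the atomistic mole ratio).

Neutralization runs after salting and supports three algorithms: add
counterions, remove co-ions, or split the correction as evenly as
possible between the two (an odd remainder goes to the addition side).
The resulting plan always closes the total system charge to exactly
zero, in integer arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .allocation import round_half_away
from .core import Box, SolventSpec

__all__ = [
    "AVOGADRO_NM3",
    "OccupancyGrid",
    "IonPlan",
    "SolvationError",
    "NeutralizationError",
    "rasterize",
    "solvent_counts",
    "salt_counts",
    "place_solvent",
    "neutralize",
]

#: Avogadro constant expressed per nm³ per mol/L: 1 M == 0.6022 molecules/nm³
AVOGADRO_NM3 = 0.6022140857

#: smallest allowed raster cell, nm (one regular water bead)
MIN_CELL = 0.5


class SolvationError(RuntimeError):
    """Raised when solvent insertion is infeasible."""


class NeutralizationError(RuntimeError):
    """Raised when the requested algorithm cannot reach zero net charge."""


@dataclass
class OccupancyGrid:
    """Rasterized box; ``free`` marks cells available for solvent."""

    box: Box
    cell: float
    free: np.ndarray  # bool, shape (nx, ny, nz)

    @property
    def n_free(self) -> int:
        return int(self.free.sum())

    @property
    def free_volume(self) -> float:
        return self.n_free * self.cell ** 3

    def cell_center(self, idx: tuple[int, int, int]) -> np.ndarray:
        return (np.asarray(idx, dtype=float) + 0.5) * self.cell


def rasterize(box: Box, solvents: Sequence[SolventSpec],
              bead_positions: Optional[np.ndarray] = None,
              bead_radii: float | np.ndarray = 0.25,
              membrane_slabs: Sequence[tuple[float, float, object]] = ()
              ) -> OccupancyGrid:
    """Build the occupancy grid for solvent insertion.

    ``membrane_slabs`` are (z_lo, z_hi, footprint) triples; a footprint
    of ``None`` blocks the slab across the whole xy plane, otherwise
    only cells whose center falls inside the (shapely) footprint are
    blocked.  A cell is also unavailable when any existing bead sphere
    overlaps it.
    """
    if not solvents:
        raise SolvationError("rasterize needs at least one solvent definition")
    cell = max(MIN_CELL, max(s.max_extent for s in solvents))
    nx = max(1, int(box.x / cell + 1e-9))
    ny = max(1, int(box.y / cell + 1e-9))
    nz = max(1, int(box.z / cell + 1e-9))
    free = np.ones((nx, ny, nz), dtype=bool)

    for z_lo, z_hi, footprint in membrane_slabs:
        lo, hi = min(z_lo, z_hi), max(z_lo, z_hi)
        k = np.arange(nz)
        z_cells = ((k + 1) * cell > lo + 1e-9) & (k * cell < hi - 1e-9)
        if footprint is None:
            free[:, :, z_cells] = False
        else:
            import shapely
            xs = (np.arange(nx) + 0.5) * cell
            ys = (np.arange(ny) + 0.5) * cell
            gx, gy = np.meshgrid(xs, ys, indexing="ij")
            inside = shapely.contains_xy(footprint, gx.ravel(), gy.ravel())
            inside = inside.reshape(nx, ny)
            mask3d = inside[:, :, None] & z_cells[None, None, :]
            free[mask3d] = False

    if bead_positions is not None and len(bead_positions):
        pos = np.asarray(bead_positions, dtype=float).reshape(-1, 3)
        radii = np.broadcast_to(np.asarray(bead_radii, dtype=float), (len(pos),))
        for (px, py, pz), r in zip(pos, radii):
            i0 = max(0, int((px - r) / cell))
            i1 = min(nx - 1, int((px + r) / cell))
            j0 = max(0, int((py - r) / cell))
            j1 = min(ny - 1, int((py + r) / cell))
            k0 = max(0, int((pz - r) / cell))
            k1 = min(nz - 1, int((pz + r) / cell))
            for i in range(i0, i1 + 1):
                for j in range(j0, j1 + 1):
                    for k in range(k0, k1 + 1):
                        # sphere/cell-box overlap by clamped distance
                        cx = min(max(px, i * cell), (i + 1) * cell)
                        cy = min(max(py, j * cell), (j + 1) * cell)
                        cz = min(max(pz, k * cell), (k + 1) * cell)
                        if (px - cx) ** 2 + (py - cy) ** 2 + (pz - cz) ** 2 <= r * r:
                            free[i, j, k] = False

    grid = OccupancyGrid(box=box, cell=cell, free=free)
    if grid.n_free == 0:
        raise SolvationError("solvation infeasible: no free cells in the box")
    return grid


def _split_total(total: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder integer split of ``total`` by positive weights."""
    wsum = sum(weights.values())
    shares = {n: w / wsum * total for n, w in weights.items()}
    counts = {n: int(math.floor(s)) for n, s in shares.items()}
    rem = total - sum(counts.values())
    order = sorted(weights, key=lambda n: shares[n] - counts[n], reverse=True)
    for n in order[:rem]:
        counts[n] += 1
    return counts


def solvent_counts(free_volume: float, specs: Sequence[SolventSpec],
                   ratio_mode: str = "beads",
                   total_molarity: Optional[float] = None) -> dict[str, int]:
    """Whole-molecule counts for each solvent species.

    A single solvent uses its own molarity.  A mixture shares one total
    molarity (``total_molarity``, default the sum over the specs) and is
    split by the ratio weights; in ``mapping`` mode each weight is first
    multiplied by the species' atoms-per-bead mapping factor, so the
    ratio is honoured at the underlying atomistic level.
    """
    if free_volume <= 0:
        raise SolvationError("free volume must be positive")
    if not specs:
        return {}
    for s in specs:
        if s.molarity < 0:
            raise ValueError(f"negative molarity for {s.name!r}")
    if len(specs) == 1:
        s = specs[0]
        m = s.molarity if total_molarity is None else total_molarity
        return {s.name: round_half_away(m * AVOGADRO_NM3 * free_volume)}
    m = total_molarity if total_molarity is not None else sum(s.molarity for s in specs)
    total = round_half_away(m * AVOGADRO_NM3 * free_volume)
    if ratio_mode == "mapping":
        weights = {s.name: s.ratio * s.mapping_factor for s in specs}
    elif ratio_mode == "beads":
        weights = {s.name: s.ratio for s in specs}
    else:
        raise ValueError(f"unknown ratio mode {ratio_mode!r}")
    return _split_total(total, weights)


def salt_counts(free_volume: float, molarity: float,
                pos_ion: SolventSpec, neg_ion: SolventSpec) -> dict[str, int]:
    """Ion counts at the target salt molarity (cation count sets the scale).

    The anion count balances the cation charge as closely as integer
    stoichiometry allows; any residue is handled by neutralization.
    """
    if molarity < 0:
        raise ValueError("salt molarity must be >= 0")
    n_pos = round_half_away(molarity * AVOGADRO_NM3 * free_volume)
    z_pos = abs(int(round(pos_ion.charge))) or 1
    z_neg = abs(int(round(neg_ion.charge))) or 1
    n_neg = round_half_away(n_pos * z_pos / z_neg)
    return {pos_ion.name: n_pos, neg_ion.name: n_neg}


def place_solvent(grid: OccupancyGrid, counts: dict[str, int], seed: int
                  ) -> list[tuple[str, np.ndarray]]:
    """Assign molecules to distinct free cells (seeded, without replacement).

    Each molecule is centered in its cell; the cells become occupied.
    """
    total = sum(counts.values())
    if total == 0:
        return []
    free_idx = np.argwhere(grid.free)
    if total > len(free_idx):
        raise SolvationError(
            f"solvation infeasible: {total} molecules requested but only "
            f"{len(free_idx)} free cells available (short by {total - len(free_idx)})")
    rng = np.random.default_rng(seed)
    chosen = free_idx[rng.choice(len(free_idx), size=total, replace=False)]
    placements: list[tuple[str, np.ndarray]] = []
    k = 0
    for name, n in counts.items():
        for _ in range(n):
            idx = tuple(chosen[k])
            placements.append((name, grid.cell_center(idx)))
            grid.free[idx] = False
            k += 1
    return placements


@dataclass
class IonPlan:
    """Ion additions/removals that close the system charge to zero."""

    add: dict[str, int] = field(default_factory=dict)
    remove: dict[str, int] = field(default_factory=dict)
    net_charge: int = 0


def neutralize(system_charge: int,
               pos_ion: SolventSpec, neg_ion: SolventSpec,
               present: Optional[dict[str, int]] = None,
               algorithm: str = "add") -> IonPlan:
    """Compute the ion plan that brings the net system charge to zero.

    ``present`` gives the removable ion counts already in the box (the
    salt placed at the target molarity); required by the ``remove`` and
    ``combined`` algorithms.  Charges per species must be integers
    (±1, ±2 typical).
    """
    present = dict(present or {})
    q = int(system_charge)
    if q == 0:
        return IonPlan()
    counter = pos_ion if q < 0 else neg_ion
    co = neg_ion if q < 0 else pos_ion
    z_counter = abs(int(round(counter.charge)))
    z_co = abs(int(round(co.charge)))
    if z_counter == 0 or z_co == 0:
        raise NeutralizationError("ion species must carry a nonzero integer charge")
    need = abs(q)

    if algorithm == "add":
        if need % z_counter:
            raise NeutralizationError(
                f"cannot neutralize a charge of {q} exactly by adding "
                f"{counter.name} (|charge| {z_counter})")
        return IonPlan(add={counter.name: need // z_counter})

    if algorithm == "remove":
        if need % z_co:
            raise NeutralizationError(
                f"cannot neutralize a charge of {q} exactly by removing "
                f"{co.name} (|charge| {z_co})")
        n = need // z_co
        if n > present.get(co.name, 0):
            raise NeutralizationError(
                f"neutralization infeasible: need to remove {n} {co.name} but only "
                f"{present.get(co.name, 0)} are present")
        return IonPlan(remove={co.name: n})

    if algorithm == "combined":
        # split the correction as evenly as possible; odd remainder goes
        # to the addition side
        max_rem = min(present.get(co.name, 0), need // z_co)
        # prefer the most even split; on a tie the addition side wins
        candidates = sorted(range(max_rem + 1),
                            key=lambda n: (abs(2 * n * z_co - need), n))
        for n_rem in candidates:
            rest = need - n_rem * z_co
            if rest % z_counter == 0:
                plan = IonPlan(add={counter.name: rest // z_counter} if rest else {},
                               remove={co.name: n_rem} if n_rem else {})
                return plan
        raise NeutralizationError(
            f"combined neutralization cannot reach zero net charge for {q} "
            f"with ion charges +{z_counter}/-{z_co}")

    raise ValueError(f"unknown neutralization algorithm {algorithm!r}")
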