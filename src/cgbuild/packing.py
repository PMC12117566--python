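"""2D lipid packing: free-area geometry, disc placement, push-force relaxation.

Each lipid is represented in the membrane plane as a disc whose radius
reflects its lipid type.  A leaflet is a polygonal region (boundary
minus pores and protein footprints); the free area A_free of that region
feeds the allocation step, and placement happens inside it:

* large-class lipids are placed semirandomly on a square grid with pitch
  matched to the largest lipid diameter;
* small-class lipids fill y-directional lines through the still
  unoccupied area, with line spacing tightened iteratively until every
  requested lipid fits.

Remaining disc overlaps are relaxed by a pairwise push scheme: discs
within a cutoff push each other apart along the centre-centre vector
with a magnitude proportional to overlap depth, lipid size, and a
per-step factor that decays linearly over the run; region edges and hole
boundaries push the same way.  A step that would increase the total
pairwise overlap is damped and, failing that, rejected, so the total
overlap depth is non-increasing over the whole relaxation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import nearest_points, unary_union

from .core import Bead, LeafletPlan, LipidType

__all__ = [
    "Disc",
    "LeafletRegion",
    "PlacementError",
    "protein_footprint",
    "free_area",
    "assign_size_classes",
    "initial_placement",
    "relax",
    "total_overlap",
    "realize_leaflet",
    "discs_to_csv",
]

#: polygonization fidelity of circular footprints: 8 segments per quarter
#: circle = 32-gon, bounding the area error of a disc by ~1%.
CIRCLE_QUAD_SEGS = 8


class PlacementError(RuntimeError):
    """Raised when the requested lipids cannot be fitted into a leaflet."""


@dataclass(frozen=True)
class Disc:
    """2D circle proxy of one placed lipid."""

    name: str
    x: float
    y: float
    radius: float

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


class LeafletRegion:
    """Polygonal placement region of one leaflet: boundary minus holes."""

    def __init__(self, boundary: Polygon | Sequence[tuple[float, float]],
                 holes: Sequence = ()):
        if not isinstance(boundary, (Polygon, MultiPolygon)):
            boundary = Polygon(boundary)
        if not boundary.is_valid or boundary.is_empty:
            raise ValueError("leaflet boundary is not a valid simple polygon")
        hole_geoms = []
        for h in holes:
            g = h if isinstance(h, (Polygon, MultiPolygon)) else Polygon(h)
            hole_geoms.append(g)
        self.boundary = boundary
        self.holes = unary_union(hole_geoms) if hole_geoms else None
        if self.holes is not None:
            self.free_geom = boundary.difference(self.holes)
        else:
            self.free_geom = boundary
        # line work used for edge forces: outer rings push inward, hole
        # rings push outward
        self._edges = shapely.boundary(self.free_geom)

    @property
    def a_free(self) -> float:
        return self.free_geom.area

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        pts = shapely.points(xy)
        return shapely.contains(self.free_geom, pts)

    def clamp_inside(self, xy: np.ndarray, eps: float = 1e-6) -> np.ndarray:
        """Project points that left the free region back onto it."""
        xy = np.array(xy, dtype=float)
        inside = self.contains_points(xy)
        if inside.all():
            return xy
        for i in np.nonzero(~inside)[0]:
            p = Point(xy[i])
            q = nearest_points(self.free_geom, p)[0]
            v = np.array([q.x - p.x, q.y - p.y])
            n = np.linalg.norm(v)
            cand = np.array([q.x, q.y]) + (v / n * eps if n > 0 else 0.0)
            if not self.free_geom.contains(Point(cand)):
                cand = np.array([q.x, q.y])
            xy[i] = cand
        return xy


def protein_footprint(positions: np.ndarray, radii: np.ndarray,
                      slab: tuple[float, float]):
    """xy footprint of the protein beads that intersect a leaflet slab.

    A bead contributes when its z interval ``[z - r, z + r]`` overlaps
    the leaflet's z extent; contributing beads are projected onto the xy
    plane as discs (32-gon approximations) and unioned.  Returns a
    (possibly empty) polygonal geometry.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), positions.shape[:1])
    z_lo, z_hi = min(slab), max(slab)
    hit = (positions[:, 2] + radii >= z_lo) & (positions[:, 2] - radii <= z_hi)
    if not hit.any():
        return Polygon()
    discs = [Point(x, y).buffer(r, quad_segs=CIRCLE_QUAD_SEGS)
             for (x, y, _), r in zip(positions[hit], radii[hit])]
    return unary_union(discs)


def free_area(region: LeafletRegion) -> float:
    """Free leaflet area in nm² (boundary minus union of holes)."""
    a = region.a_free
    if a <= 0:
        warnings.warn("leaflet holes cover the entire boundary; free area is 0",
                      stacklevel=2)
        return 0.0
    return a


def assign_size_classes(types: dict[str, LipidType]) -> dict[str, LipidType]:
    """Split lipid types into large/small at the median packing radius.

    Types at or above the median are "large" (grid placement); the rest
    are "small" (line placement).  Returns new LipidType objects.
    """
    radii = sorted(t.radius for t in types.values())
    median = radii[len(radii) // 2] if len(radii) % 2 else 0.5 * (
        radii[len(radii) // 2 - 1] + radii[len(radii) // 2])
    return {
        name: replace(t, size_class="large" if t.radius >= median else "small")
        for name, t in types.items()
    }


def _grid_cells(region: LeafletRegion, pitch: float) -> np.ndarray:
    """Centers of grid cells of the given pitch lying inside the region."""
    minx, miny, maxx, maxy = region.free_geom.bounds
    xs = np.arange(minx + pitch / 2, maxx, pitch)
    ys = np.arange(miny + pitch / 2, maxy, pitch)
    if len(xs) == 0 or len(ys) == 0:
        return np.empty((0, 2))
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    return cells[region.contains_points(cells)]


def initial_placement(plan: LeafletPlan, region: LeafletRegion,
                      types: dict[str, LipidType], seed: int) -> list[Disc]:
    """Place every lipid of the plan as a disc inside the region.

    Large lipids occupy randomly chosen cells of a square grid whose
    pitch starts at twice the largest large-lipid radius; small lipids
    are threaded onto vertical (y-directional) lines through the area the
    grid left unoccupied.  Both stages tighten their spacing iteratively
    until all requested lipids fit, and raise :class:`PlacementError` if
    the geometry cannot host them.
    """
    rng = np.random.default_rng(seed)
    n_total = sum(plan.counts.values())
    if n_total == 0:
        return []
    if region.a_free <= 0:
        raise PlacementError("placement infeasible: leaflet free area is zero")

    large_names = [n for n, c in plan.counts.items()
                   if c > 0 and types[n].size_class == "large"]
    small_names = [n for n, c in plan.counts.items()
                   if c > 0 and types[n].size_class == "small"]
    discs: list[Disc] = []

    large_xy = np.empty((0, 2))
    large_r = np.empty(0)
    if large_names:
        n_large = sum(plan.counts[n] for n in large_names)
        r_max = max(types[n].radius for n in large_names)
        pitch = 2.0 * r_max
        # refuse to compress the grid below half a lipid radius: that is
        # already far denser than any physically meaningful APL
        pitch_floor = max(0.05, 0.5 * r_max)
        while True:
            cells = _grid_cells(region, pitch)
            if len(cells) >= n_large:
                break
            pitch *= 0.85
            if pitch < pitch_floor:
                raise PlacementError(
                    f"placement infeasible: cannot fit {n_large} large lipids "
                    f"into a free area of {region.a_free:.3f} nm²")
        chosen = cells[rng.choice(len(cells), size=n_large, replace=False)]
        labels = [n for n in large_names for _ in range(plan.counts[n])]
        rng.shuffle(labels)
        for (x, y), name in zip(chosen, labels):
            discs.append(Disc(name, float(x), float(y), types[name].radius))
        large_xy = chosen
        large_r = np.array([types[n].radius for n in labels])

    if small_names:
        n_small = sum(plan.counts[n] for n in small_names)
        r_small = max(types[n].radius for n in small_names)
        minx, miny, maxx, maxy = region.free_geom.bounds
        spacing = 2.0 * r_small
        clearance = (large_r.max() + r_small) if len(large_r) else 0.0
        tree = cKDTree(large_xy) if len(large_xy) else None
        while True:
            xs = np.arange(minx + spacing / 2, maxx, spacing)  # the lines
            ys = np.arange(miny + spacing / 2, maxy, spacing)  # points on a line
            gx, gy = np.meshgrid(xs, ys, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel()])
            if len(pts):
                pts = pts[region.contains_points(pts)]
            if len(pts) and tree is not None and clearance > 0:
                blocked = tree.query_ball_point(pts, r=clearance)
                pts = pts[[not b for b in blocked]]
            if len(pts) >= n_small:
                break
            # tighten the line raster; when that bottoms out, give up the
            # clearance around large lipids and let relaxation sort it out
            if spacing > max(0.05, 0.5 * r_small):
                spacing *= 0.85
            elif clearance > 0:
                clearance *= 0.7
                if clearance < 0.05:
                    clearance = 0.0
            else:
                raise PlacementError(
                    f"placement infeasible: cannot fit {n_small} small lipids "
                    f"into the unoccupied leaflet area")
        chosen = pts[rng.choice(len(pts), size=n_small, replace=False)]
        labels = [n for n in small_names for _ in range(plan.counts[n])]
        rng.shuffle(labels)
        for (x, y), name in zip(chosen, labels):
            discs.append(Disc(name, float(x), float(y), types[name].radius))

    return discs


def total_overlap(discs: Sequence[Disc]) -> float:
    """Total pairwise overlap depth Σ max(0, r_i + r_j − d_ij), nm."""
    if len(discs) < 2:
        return 0.0
    xy = np.array([[d.x, d.y] for d in discs])
    r = np.array([d.radius for d in discs])
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=2.0 * r.max(), output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(xy[i] - xy[j], axis=1)
    return float(np.maximum(0.0, r[i] + r[j] - d).sum())


def _pair_forces(xy: np.ndarray, r: np.ndarray, lam: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Displacements from the pairwise push force at step factor lam."""
    disp = np.zeros_like(xy)
    if len(xy) < 2:
        return disp
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=1.2 * 2.0 * r.max(), output_type="ndarray")
    if len(pairs) == 0:
        return disp
    i, j = pairs[:, 0], pairs[:, 1]
    diff = xy[i] - xy[j]
    d = np.linalg.norm(diff, axis=1)
    rsum = r[i] + r[j]
    within = d < 1.2 * rsum
    i, j, diff, d, rsum = i[within], j[within], diff[within], d[within], rsum[within]
    depth = np.maximum(0.0, rsum - d)
    active = depth > 0
    i, j, diff, d, rsum, depth = (a[active] for a in (i, j, diff, d, rsum, depth))
    if len(i) == 0:
        return disp
    coincident = d < 1e-12
    if coincident.any():  # coincident centers: random push direction
        ang = rng.uniform(0, 2 * np.pi, size=int(coincident.sum()))
        diff[coincident] = np.column_stack([np.cos(ang), np.sin(ang)])
        d[coincident] = 1.0
    u = diff / d[:, None]
    mag = depth * (rsum / 2.0) * lam
    np.add.at(disp, i, u * mag[:, None])
    np.add.at(disp, j, -u * mag[:, None])
    return disp


def _edge_forces(xy: np.ndarray, r: np.ndarray, region: LeafletRegion,
                 lam: float) -> np.ndarray:
    """Push from region edges (boundary and holes) on penetrating discs."""
    disp = np.zeros_like(xy)
    pts = shapely.points(xy)
    dist = shapely.distance(pts, region._edges)
    pen = r - dist
    for k in np.nonzero(pen > 0)[0]:
        p = Point(xy[k])
        q = nearest_points(region._edges, p)[0]
        v = np.array([p.x - q.x, p.y - q.y])
        n = np.linalg.norm(v)
        if n < 1e-12:
            continue
        if not region.free_geom.contains(p):
            v = -v  # center already outside: push back in
        disp[k] += v / n * pen[k] * r[k] * lam
    return disp


def relax(discs: Sequence[Disc], region: LeafletRegion,
          tolerance: float = 0.005, max_steps: int = 100,
          seed: int = 0,
          overlap_history: Optional[list] = None) -> tuple[list[Disc], bool]:
    """Push-force overlap relaxation.

    Returns the relaxed discs and a convergence flag.  The step factor
    decays linearly from 0.5 to 0.05 across the run; a step whose
    proposed displacements would increase the total pairwise overlap is
    halved up to six times and then skipped, making the overlap depth
    non-increasing throughout.  Centers are clamped into the free region
    after every step, so containment holds at all times.  Convergence:
    maximum per-disc displacement below ``tolerance`` (nm).

    Pass a list as ``overlap_history`` to record the total pairwise
    overlap depth every 10 steps (plus start and end).
    """
    discs = list(discs)
    if len(discs) == 0:
        return [], True
    rng = np.random.default_rng(seed)
    xy = np.array([[d.x, d.y] for d in discs], dtype=float)
    r = np.array([d.radius for d in discs], dtype=float)
    xy = region.clamp_inside(xy)

    def pair_energy(p: np.ndarray) -> float:
        return total_overlap([Disc("x", x, y, ri) for (x, y), ri in zip(p, r)])

    energy = pair_energy(xy)
    if overlap_history is not None:
        overlap_history.append(energy)
    converged = False
    for step in range(max_steps):
        lam = 0.5 - (0.5 - 0.05) * (step / max(max_steps - 1, 1))
        disp = _pair_forces(xy, r, lam, rng) + _edge_forces(xy, r, region, lam)
        moved = False
        for _ in range(7):
            cand = region.clamp_inside(xy + disp)
            cand_energy = pair_energy(cand)
            if cand_energy <= energy + 1e-12:
                max_disp = float(np.linalg.norm(cand - xy, axis=1).max())
                xy, energy, moved = cand, cand_energy, True
                break
            disp *= 0.5
        if not moved:
            max_disp = 0.0
        if overlap_history is not None and (step + 1) % 10 == 0:
            overlap_history.append(energy)
        if max_disp < tolerance:
            converged = True
            break
    if overlap_history is not None:
        overlap_history.append(energy)
    out = [replace(d, x=float(p[0]), y=float(p[1])) for d, p in zip(discs, xy)]
    return out, converged


def realize_leaflet(discs: Sequence[Disc], types: dict[str, LipidType],
                    z_anchor: float, side: str, seed: int
                    ) -> list[tuple[str, list[Bead], np.ndarray]]:
    """Turn relaxed discs into 3D lipid bead coordinates.

    Each disc is replaced by its template beads rotated by a random
    angle about z, mirrored in z for the lower leaflet, and translated
    to (center, z_anchor).  Returns one (lipid name, template beads,
    coordinates) triple per lipid, in disc order.
    """
    rng = np.random.default_rng(seed)
    flip = -1.0 if side == "lower" else 1.0
    out = []
    for d in discs:
        t = types[d.name]
        local = np.array([b.position for b in t.beads], dtype=float)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        c, s = math.cos(theta), math.sin(theta)
        rot = local.copy()
        rot[:, 0] = c * local[:, 0] - s * local[:, 1]
        rot[:, 1] = s * local[:, 0] + c * local[:, 1]
        rot[:, 2] = flip * local[:, 2]
        rot += np.array([d.x, d.y, z_anchor])
        out.append((d.name, t.beads, rot))
    return out


def discs_to_csv(discs: Sequence[Disc], path: str) -> None:
    """Debug export of disc centers and radii."""
    import pandas as pd

    pd.DataFrame([{"name": d.name, "x": d.x, "y": d.y, "radius": d.radius}
                  for d in discs]).to_csv(path, index=False)
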