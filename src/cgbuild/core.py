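"""Domain types and the declarative system specification.

Every build stage consumes these types.  Units are nanometres and
elementary charges throughout; conversion to other units (Å for PDB)
happens only at file boundaries.

A system is described by a single :class:`SystemSpec`: a box, zero or
more membranes (each one or two leaflets), optional proteins, optional
solvation and flooding requests.  The spec is a plain data object that
can be round-tripped through a flat YAML document (see
:func:`spec_to_dict` / :func:`spec_from_dict`), mirroring the
one-command philosophy of the builder: everything needed to reproduce a
system lives in one declaration plus one seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Bead",
    "Box",
    "LipidType",
    "LeafletSpec",
    "LeafletPlan",
    "SolventSpec",
    "MembraneSpec",
    "ProteinSpec",
    "SolvationRequest",
    "FloodingRequest",
    "SystemSpec",
    "Diagnostic",
    "validate_spec",
    "build_order",
    "derive_seed",
    "spec_to_dict",
    "spec_from_dict",
]


@dataclass(frozen=True)
class Bead:
    """One coarse-grained particle of a molecule template.

    ``position`` is the local coordinate in nm relative to the molecule
    origin; ``charge`` is in elementary charges.
    """

    name: str
    resname: str
    position: tuple[float, float, float]
    charge: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"bead {self.name!r} has non-finite position")
        if not np.isfinite(self.charge):
            raise ValueError(f"bead {self.name!r} has non-finite charge")


@dataclass(frozen=True)
class Box:
    """Orthorhombic simulation box, side lengths in nm."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        for axis in ("x", "y", "z"):
            v = getattr(self, axis)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"box.{axis} must be strictly positive, got {v}")

    @property
    def volume(self) -> float:
        return self.x * self.y * self.z


@dataclass
class LipidType:
    """A named lipid template.

    ``radius`` is the 2D packing radius used by the disc-packing engine;
    ``size_class`` ("large" or "small") selects grid vs line placement.
    ``tail_beads`` flags the beads that span the hydrophobic interior,
    used to derive the membrane's solvent-excluded slab.
    """

    name: str
    beads: list[Bead]
    radius: float
    size_class: str = "large"
    tail_beads: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.beads:
            raise ValueError(f"lipid {self.name!r} has an empty bead list")
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValueError(f"lipid {self.name!r} radius must be > 0")
        if self.size_class not in ("large", "small"):
            raise ValueError(f"lipid {self.name!r}: unknown size class {self.size_class!r}")

    @property
    def charge(self) -> float:
        return sum(b.charge for b in self.beads)

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass
class LeafletSpec:
    """Requested composition and geometry of one leaflet.

    ``composition`` maps lipid names to positive ratio weights (the
    interlipid ratio w); ``apl`` is the area per lipid in nm²;
    ``boundary`` is a simple polygon in the xy plane (``None`` means the
    full box cross-section) and ``holes`` are polygons (pores, patches)
    subtracted from it.
    """

    side: str  # "upper" | "lower"
    z_anchor: float
    composition: dict[str, float]
    apl: float
    boundary: Optional[list[tuple[float, float]]] = None
    holes: list[list[tuple[float, float]]] = field(default_factory=list)

    def __post_init__(self):
        if self.side not in ("upper", "lower"):
            raise ValueError(f"leaflet side must be 'upper' or 'lower', got {self.side!r}")
        if not (np.isfinite(self.apl) and self.apl > 0):
            raise ValueError(f"leaflet apl must be > 0, got {self.apl}")
        for name, w in self.composition.items():
            if not (np.isfinite(w) and w > 0):
                raise ValueError(f"ratio weight for {name!r} must be positive, got {w}")


@dataclass
class LeafletPlan:
    """Resolved integer lipid counts for one leaflet.

    ``n_max`` is the rounded total allowed by A_free/APL, ``n_min`` the
    sum of the per-type floors; the plan always sums to ``n_max``.
    """

    counts: dict[str, int]
    n_min: int
    n_max: int
    a_free: float

    def __post_init__(self):
        total = sum(self.counts.values())
        if total != self.n_max:
            raise ValueError(f"plan counts sum to {total}, expected n_max={self.n_max}")
        if self.n_min > self.n_max:
            raise ValueError("n_min exceeds n_max")


@dataclass
class SolventSpec:
    """A solvent, ion or solute molecule with its insertion parameters.

    ``mapping_factor`` is the number of underlying atoms represented per
    bead, consumed by the mapping-aware mixed-solvent ratio mode.
    ``ratio`` is the relative weight of this species in a mixture.
    """

    name: str
    beads: list[Bead]
    molarity: float = 0.0
    mapping_factor: int = 1
    role: str = "solvent"  # solvent | positive-ion | negative-ion | solute
    ratio: float = 1.0

    def __post_init__(self):
        if self.molarity < 0:
            raise ValueError(f"molarity of {self.name!r} must be >= 0")
        if self.mapping_factor < 1:
            raise ValueError(f"mapping_factor of {self.name!r} must be >= 1")
        if self.role not in ("solvent", "positive-ion", "negative-ion", "solute"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def charge(self) -> float:
        return sum(b.charge for b in self.beads)

    @property
    def max_extent(self) -> float:
        """Largest intra-molecular bead-pair distance, nm."""
        pos = np.array([b.position for b in self.beads], dtype=float)
        if len(pos) == 1:
            return 0.0
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        return float(d.max())


@dataclass
class MembraneSpec:
    """One membrane: one or two leaflets around a z midplane."""

    leaflets: list[LeafletSpec]
    center_z: float = 0.0

    def __post_init__(self):
        if not 1 <= len(self.leaflets) <= 2:
            raise ValueError("a membrane needs one or two leaflets")
        sides = [lf.side for lf in self.leaflets]
        if len(set(sides)) != len(sides):
            raise ValueError("duplicate leaflet side in one membrane")


@dataclass
class ProteinSpec:
    """A protein coordinate file plus a rigid placement transform."""

    filename: str
    translate: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotate_z_deg: float = 0.0
    moleculetype: Optional[str] = None


@dataclass
class SolvationRequest:
    solvents: list[SolventSpec] = field(default_factory=list)
    pos_ion: Optional[SolventSpec] = None
    neg_ion: Optional[SolventSpec] = None
    salt_molarity: float = 0.0
    neutralize: str = "add"  # add | remove | combined
    ratio_mode: str = "beads"  # beads | mapping

    def __post_init__(self):
        if self.neutralize not in ("add", "remove", "combined"):
            raise ValueError(f"unknown neutralization algorithm {self.neutralize!r}")
        if self.ratio_mode not in ("beads", "mapping"):
            raise ValueError(f"unknown ratio mode {self.ratio_mode!r}")


@dataclass
class FloodingRequest:
    solute: SolventSpec
    count: Optional[int] = None
    molarity: Optional[float] = None

    def __post_init__(self):
        if (self.count is None) == (self.molarity is None):
            raise ValueError("flooding needs exactly one of count or molarity")


@dataclass
class SystemSpec:
    """The full declarative description of one build."""

    box: Box
    membranes: list[MembraneSpec] = field(default_factory=list)
    proteins: list[ProteinSpec] = field(default_factory=list)
    solvation: Optional[SolvationRequest] = None
    flooding: list[FloodingRequest] = field(default_factory=list)
    out_gro: str = "system.gro"
    out_top: Optional[str] = None
    out_pdb: Optional[str] = None
    seed: int = 1


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "fatal" | "warning"
    message: str

    @property
    def fatal(self) -> bool:
        return self.level == "fatal"


def validate_spec(spec: SystemSpec) -> list[Diagnostic]:
    """Check a system spec for buildability.

    Returns an empty list when the spec is valid; otherwise a list of
    diagnostics, each tagged fatal or warning.  Fatal diagnostics abort
    the build before any geometry is produced.
    """
    out: list[Diagnostic] = []
    try:
        Box(spec.box.x, spec.box.y, spec.box.z)
    except ValueError as exc:
        out.append(Diagnostic("fatal", str(exc)))
        return out

    if not (spec.membranes or spec.proteins or spec.flooding or
            (spec.solvation and spec.solvation.solvents)):
        out.append(Diagnostic("fatal", "nothing to build: the spec names a box but no "
                                       "membrane, protein, solvent or solute"))

    anchors = sorted(m.center_z for m in spec.membranes)
    for a, b in zip(anchors, anchors[1:]):
        if b - a < 1e-9:
            out.append(Diagnostic("fatal", f"overlapping membranes: stacked membranes share "
                                           f"center z = {a:g} nm"))
    for m in spec.membranes:
        for lf in m.leaflets:
            if not lf.composition:
                out.append(Diagnostic("fatal", f"leaflet {lf.side!r} at z={lf.z_anchor:g} "
                                               f"has an empty composition"))
            if not (0.0 <= lf.z_anchor <= spec.box.z):
                out.append(Diagnostic("warning", f"leaflet anchor z={lf.z_anchor:g} lies "
                                                 f"outside the box"))
    if spec.solvation is not None:
        for s in spec.solvation.solvents:
            if s.molarity == 0 and s.ratio <= 0:
                out.append(Diagnostic("warning", f"solvent {s.name!r} has zero molarity "
                                                 f"and no ratio weight"))
        if spec.solvation.salt_molarity > 0 and (
                spec.solvation.pos_ion is None or spec.solvation.neg_ion is None):
            out.append(Diagnostic("fatal", "salt molarity requested without both ion species"))
    return out


#: serial stage order of one build
STAGES = ("protein", "membrane", "flooding", "solvent", "ions", "write")


def build_order(spec: SystemSpec) -> list[str]:
    """Deterministic serial stage list for a valid spec.

    Proteins first, then membranes leaflet by leaflet sorted by ascending
    z anchor, then flooding solutes, solvent, ions, and the writers.
    Identical spec + seed always yields an identical order.
    """
    order: list[str] = []
    if spec.proteins:
        order.append("protein")
    for mem in sorted(spec.membranes, key=lambda m: m.center_z):
        order.append("membrane")
    if spec.flooding:
        order.append("flooding")
    if spec.solvation and spec.solvation.solvents:
        order.append("solvent")
    if spec.solvation and (spec.solvation.salt_molarity > 0 or
                           spec.solvation.pos_ion or spec.solvation.neg_ion):
        order.append("ions")
    order.append("write")
    return order


def derive_seed(master_seed: int, stage: str) -> int:
    """Child seed for a stochastic stage, stable across platforms.

    CRC32 of "master:stage" folded below 2**31 — each stage draws from
    its own stream, so reordering or skipping stages never shifts the
    randomness of the others.
    """
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# flat config round-trip


def spec_to_dict(spec: SystemSpec) -> dict:
    """Serialize a SystemSpec to one flat mapping (the config format)."""

    def leaflet(lf: LeafletSpec) -> dict:
        return {
            "side": lf.side,
            "z_anchor": lf.z_anchor,
            "composition": dict(lf.composition),
            "apl": lf.apl,
            "boundary": [list(p) for p in lf.boundary] if lf.boundary else None,
            "holes": [[list(p) for p in h] for h in lf.holes],
        }

    def solvent(s: SolventSpec) -> dict:
        return {
            "name": s.name,
            "beads": [[b.name, b.resname, list(b.position), b.charge] for b in s.beads],
            "molarity": s.molarity,
            "mapping_factor": s.mapping_factor,
            "role": s.role,
            "ratio": s.ratio,
        }

    d: dict = {
        "box": [spec.box.x, spec.box.y, spec.box.z],
        "membranes": [
            {"center_z": m.center_z, "leaflets": [leaflet(lf) for lf in m.leaflets]}
            for m in spec.membranes
        ],
        "proteins": [
            {"filename": p.filename, "translate": list(p.translate),
             "rotate_z_deg": p.rotate_z_deg, "moleculetype": p.moleculetype}
            for p in spec.proteins
        ],
        "flooding": [
            {"solute": solvent(f.solute), "count": f.count, "molarity": f.molarity}
            for f in spec.flooding
        ],
        "out_gro": spec.out_gro,
        "out_top": spec.out_top,
        "out_pdb": spec.out_pdb,
        "seed": spec.seed,
    }
    if spec.solvation is not None:
        sv = spec.solvation
        d["solvation"] = {
            "solvents": [solvent(s) for s in sv.solvents],
            "pos_ion": solvent(sv.pos_ion) if sv.pos_ion else None,
            "neg_ion": solvent(sv.neg_ion) if sv.neg_ion else None,
            "salt_molarity": sv.salt_molarity,
            "neutralize": sv.neutralize,
            "ratio_mode": sv.ratio_mode,
        }
    else:
        d["solvation"] = None
    return d


def spec_from_dict(d: dict) -> SystemSpec:
    """Inverse of :func:`spec_to_dict`."""

    def leaflet(ld: dict) -> LeafletSpec:
        return LeafletSpec(
            side=ld["side"],
            z_anchor=ld["z_anchor"],
            composition=dict(ld["composition"]),
            apl=ld["apl"],
            boundary=[tuple(p) for p in ld["boundary"]] if ld.get("boundary") else None,
            holes=[[tuple(p) for p in h] for h in ld.get("holes", [])],
        )

    def solvent(sd: Optional[dict]) -> Optional[SolventSpec]:
        if sd is None:
            return None
        return SolventSpec(
            name=sd["name"],
            beads=[Bead(b[0], b[1], tuple(b[2]), b[3]) for b in sd["beads"]],
            molarity=sd["molarity"],
            mapping_factor=sd["mapping_factor"],
            role=sd["role"],
            ratio=sd.get("ratio", 1.0),
        )

    solvation = None
    if d.get("solvation") is not None:
        sv = d["solvation"]
        solvation = SolvationRequest(
            solvents=[solvent(s) for s in sv["solvents"]],
            pos_ion=solvent(sv.get("pos_ion")),
            neg_ion=solvent(sv.get("neg_ion")),
            salt_molarity=sv.get("salt_molarity", 0.0),
            neutralize=sv.get("neutralize", "add"),
            ratio_mode=sv.get("ratio_mode", "beads"),
        )
    return SystemSpec(
        box=Box(*d["box"]),
        membranes=[
            MembraneSpec(leaflets=[leaflet(ld) for ld in md["leaflets"]],
                         center_z=md["center_z"])
            for md in d.get("membranes", [])
        ],
        proteins=[
            ProteinSpec(filename=pd["filename"], translate=tuple(pd["translate"]),
                        rotate_z_deg=pd.get("rotate_z_deg", 0.0),
                        moleculetype=pd.get("moleculetype"))
            for pd in d.get("proteins", [])
        ],
        solvation=solvation,
        flooding=[
            FloodingRequest(solute=solvent(fd["solute"]), count=fd.get("count"),
                            molarity=fd.get("molarity"))
            for fd in d.get("flooding", [])
        ],
        out_gro=d.get("out_gro", "system.gro"),
        out_top=d.get("out_top"),
        out_pdb=d.get("out_pdb"),
        seed=d.get("seed", 1),
    )
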