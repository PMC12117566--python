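# Methods

This note records the model behind `cgbuild`, the defaults that matter,
and the design choices made where more than one reasonable construction
exists.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Lipid counting and allocation

A leaflet's lipid budget is `N_max = [A_free/APL]` with `[·]` denoting
round-half-away-from-zero.  Half-away rounding (rather than banker's
rounding) was chosen because it matches the colloquial "nearest integer"
and behaves identically across platforms; the choice only matters on
exact .5 boundaries.  The error of `N_max` against the ideal real count
`A_free/APL` is at most 0.5 lipids, so the relative count deviation
falls below 1% as soon as a leaflet holds ≥ 50 lipids — for APL
0.6 nm² that is a 6×6 nm² patch.

Per-type floors `⌊w_i/Σw · N_max⌋` guarantee no type is over-allocated;
the top-up then repeatedly increments the type with the largest relative
deficit `(ideal_i − n_i)/ideal_i`, ties broken by the declaration order
of the composition (deterministic and user-controllable).  Because each
increment strictly decreases the chosen type's deficit and deficits are
per-type decreasing step functions, the greedy fill minimizes the worst
relative deficit over all floor-respecting compositions; the test suite
confirms this by exhaustive enumeration of all ≤4-type instances with
weights 1–9 and totals ≤ 30 (221 400 instances).  An alternative
absolute-deficit priority is available behind a flag; it favours
abundant types and is not the default.

The double-rounded reference formula `[x/APL]·[y/APL]` is implemented
literally, as published for the *insane* tool, solely as the comparison
baseline of the accuracy sweep.  As printed it divides a length by an
area, which is dimensionally inconsistent with a per-row count; we
deliberately do not "repair" it (e.g. to `x/√APL`), because the point of
the sweep is to quantify the published formula's behaviour, and any
repair would be a guess.  Its literal deviation from ideal is
correspondingly large (tens of percent) and does not vanish with patch
size.

## Free area and protein footprints

A leaflet region is a simple polygon (default: the box cross-section)
minus the union of hole polygons — user pores plus protein footprints.
A protein bead contributes to a leaflet's footprint when its z interval
`[z−r, z+r]` intersects that leaflet's slab; contributing beads are
projected to xy discs approximated by 32-gons (area error ≤ ~1%) and
unioned.  Checking beads against each leaflet separately, rather than
the whole membrane, lets hourglass-shaped proteins carve different areas
from the two leaflets.

## Placement and relaxation

Large-class lipids (packing radius at or above the median of the
leaflet's types) occupy cells of a square grid with pitch `2·r_max`,
randomly chosen with the stage seed; if the region offers too few cells
the pitch shrinks geometrically (×0.85), with a hard floor of half a
lipid radius below which placement is declared infeasible.  Small-class
lipids fill vertical lines through the area not claimed by the grid,
with line spacing tightened the same way and, as a last resort, the
clearance around large lipids waived (relaxation then resolves the
contacts).

The packing radius of a template is half its maximal xy bead-pair
distance plus 0.1 nm of contact padding — the template geometry itself
fixes the disc size, since no universal formula exists for "the"
diameter of a lipid type.

Relaxation: discs within `1.2·(r_i+r_j)` push each other apart along the
centre line with displacement `depth · (r_i+r_j)/2 · λ(step)`; region
edges and hole boundaries push penetrating discs the same way.  The step
factor λ decays linearly from 0.5 to 0.05 over the run (default 100
steps, tolerance 0.005 nm): large early moves, fine late adjustment.
These constants are this package's own force schedule — chosen so all
fixture systems converge — not a reconstruction of any published one.
Two safeguards make the scheme robust: (i) a proposed step that would
increase the total pairwise overlap is halved up to six times and then
skipped, so the overlap depth is monotone non-increasing throughout;
(ii) after every step centres are projected back into the free region,
so containment is unconditional.  There is no periodic wrap — edges
push, and periodicity is the simulation engine's business.  Coincident
centres get a seeded random push direction.

After relaxation each disc is replaced by its template beads, rotated by
a seeded random angle about z, mirrored in z for the lower leaflet, and
translated to the leaflet's anchor plane (head plane at
`center ± template height`).

## Solvation and neutralization

The raster cell edge is the largest intra-molecular bead distance over
the requested solvents, floored at 0.5 nm (one CG water bead).  Cells
overlapped by any existing bead sphere, or intersecting a membrane's
hydrophobic slab (z range of tail beads ± 0.15 nm, over the membrane
footprint minus pores), are unavailable.  Counts use
`N_A = 0.6022140857 nm⁻³ M⁻¹`: `N = [M · N_A · V_free]`, counting whole
molecules, not beads.  Consequently the realized concentration is within
one molecule of the request whenever the request fits the raster.  The
raster holds at most one molecule per cell (8 molecules/nm³ at the
0.5 nm floor); a denser request — e.g. bulk water quoted at its
atomistic 55.5 M — saturates the free volume instead: every free cell is
filled and a warning is logged.  This is intentional: a fully solvated
box is the physically sensible reading of "fill with water".

Mixtures share one total molarity (by default the sum of the specs'
molarities) split by ratio weights; in mapping mode each weight is first
multiplied by the species' atoms-per-bead factor, honouring the ratio at
the atomistic level (50:50 with factors 4:1 → 80:20 molecules).  Integer
splitting uses largest remainders, ties by declaration order.

Salting inserts the cation count `[M·N_A·V_free]` and the
charge-balancing anion count first; neutralization then closes the exact
integer net charge by one of three algorithms: **add** counterions
(default — never fails on compatible parity), **remove** co-ions
(errors if too few are present), or **combined**, which splits the
correction as evenly as possible between additions and removals, odd
remainder to the addition side; with mixed valences the split search
also repairs parity (e.g. −5 with Ca²⁺/Cl⁻ → remove 1 Cl⁻, add 2 Ca²⁺).
A correction that no integer combination can close (odd charge, only
divalent species) raises an error rather than leaving a residual charge.

## Topology and coordinates

Only `#include`, `[moleculetype]`, `[atoms]`, `[system]` and
`[molecules]` are interpreted; includes resolve depth-first relative to
the including file, duplicate moleculetype names are an error, and
`#ifdef` blocks pass through unevaluated (their charges are ignored with
a warning).  The output `[molecules]` ledger lists the built composition
in build order with consecutive runs merged, so the ledger bead total
always equals the GRO atom count.  GRO I/O uses the fixed-width GROMACS
dialect (nm, 3 decimals, numbers wrapping at 100 000); PDB output (Å) is
secondary.

## Determinism

The build is a pure function of (spec, seed).  Each stochastic stage
derives a child seed as `crc32("master:stage") & 0x7fffffff`, so
reordering or omitting stages never perturbs another stage's stream, and
identical specs produce byte-identical files.

## Synthetic fixtures and what tests do not show

The fixture generator supplies idealized templates: lipids assembled
from a 5-fragment mini-library (beads on 0.3 nm lattices), single-bead
water/ions, a two-bead solute, and cylinder/hourglass bead-stack
proteins.  They exercise every algorithmic contract — allocation,
footprints, packing, solvation, charge closure, I/O — but carry no
force-field realism: passing tests say nothing about the physical
accuracy of any particular lipid parameterization, equilibrium APLs, or
the behaviour of real protein shapes beyond the convex/concave cases the
toys cover.  Choosing good APL inputs remains the user's task; for
asymmetric membranes a sensible workflow is to pre-equilibrate two
symmetric membranes (one per leaflet composition) in short simulations
and reuse the relaxed APLs.

## Problem sizes

The accuracy sweep covers 4–51 nm in 0.05 nm steps (941 patch sizes);
the allocation oracle enumerates 221 400 instances; the packing batch
runs 50 randomized leaflets of up to 500 lipids with pores and
footprints; end-to-end builds use 6–8 nm boxes with hundreds to a few
thousand beads.  These sizes make the whole suite run in well under a
minute while covering every code path; nothing in the algorithms is
specific to them.

## Known limitations

Flat membranes only (no curvature, no vesicles); no dynamic leaflet
segmentation for very large patches; solvent insertion is cell-centred
without local density refinement; multi-tail geometry places tails at
their anchor points without torsional chemistry; `#ifdef` topology
branches are not evaluated; the combined neutralization split is exact
but not unique when valences differ (the most even feasible split is
chosen deterministically).
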