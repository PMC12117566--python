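# cgbuild

A builder for coarse-grained (CG) membrane/solvent/protein simulation
systems in the Martini style.  One declarative specification — box,
leaflet compositions with area per lipid (APL), optional proteins,
solvents and ions with molarities — is turned into a simulation-ready
GROMACS coordinate (`.gro`) and topology (`.top`) pair in a single
command.

## The problem

A flat bilayer patch must be built "from scratch" from a handful of
numbers: patch size, lipid types and their ratios, and the APL.  Because
a membrane can only hold a whole number of lipids, naive rounding drifts
away from the requested APL and lipid ratios — noticeably so in small
patches and in asymmetric or many-component membranes.  `cgbuild`
minimizes those integer-rounding errors by construction:

* **Total count.** With free leaflet area `A_free` (boundary minus pores
  and protein footprints) the total is the nearest integer

  `N_max = [A_free / APL]`,

  which bounds the count error by 0.5 lipids at any patch size.  For
  comparison the package also implements, verbatim, the double-rounded
  per-axis formula used by the *insane* bilayer tool,
  `N = [x/APL]·[y/APL]`, whose error does not vanish with patch size.

* **Per-type allocation.** Each lipid type `i` with ratio weight `w_i`
  first receives `⌊w_i/Σw · N_max⌋` lipids (their sum is `N_min`); the
  remaining `N_max − N_min` lipids go one at a time to the type with the
  largest *relative* deficit `(ideal_i − n_i)/ideal_i`.  This greedy
  fill provably attains the minimal worst relative deficit among all
  integer compositions that respect the floors.

* **Placement.** Lipids become discs in the membrane plane: large types
  on a randomized grid, small types on y-directional lines through the
  remaining area, followed by a pairwise push-force relaxation (with
  edge forces from the patch boundary and pores) that monotonically
  reduces the total overlap.

* **Solvation.** The box is rasterized at the size of the largest
  solvent molecule; cells under existing beads or inside the membrane's
  hydrophobic slab are excluded, and the solvent count follows the
  molarity applied to the free volume only: `N = [M · N_A · V_free]`.
  Ions are added at the target salt molarity and the system is then
  neutralized exactly (add counterions, remove co-ions, or a combined
  even split).

## Worked example

Build a 6×6 nm² neutral bilayer at APL 0.6 nm² in a 10 nm-tall box,
solvate, salt at 0.15 M and neutralize:

```sh
cgbuild build --box 6 6 10 \
    --membrane lipid:LARG:1,apl:0.6,center:5 \
    --solvation solvent:W:6.0,salt:0.15,neutralize:add \
    --out-gro system.gro --out-top system.top --seed 7
```

prints

```
stage order: membrane -> solvent -> ions -> write
membrane z=5 lower leaflet: A_free=36.00 nm², n_max=60 (LARG:60), relaxation converged
membrane z=5 upper leaflet: A_free=36.00 nm², n_max=60 (LARG:60), relaxation converged
solvent: free volume 193.0 nm³, counts W:1162
salt: NA:4, CL:4
neutralization (add): charge +0 -> add {}, remove {}; net +0
wrote: system.gro, system.top
```

Each leaflet gets exactly 60 lipids (36 nm² / 0.6 nm² — the ideal count
is an integer here, so the deviation is zero); 1162 water beads realize
6.0 M in the 193 nm³ of box volume not occupied by the membrane's
hydrophobic interior; 4 Na⁺/4 Cl⁻ realize 0.15 M salt; the system is
neutral, so neutralization adds nothing.  The `[ molecules ]` ledger of
`system.top` lists the built composition in build order and its bead
total equals the atom count of `system.gro`.

The same spec can live in a YAML file (`cgbuild build --config
spec.yaml`); `cgbuild fixtures` writes the synthetic template set,
`cgbuild library '*'` lists available fragments/molecules, and `cgbuild
craft` emits a single molecule's structure without a system build — for
example an assembled two-tail lipid from the head/linker/tail fragment
library.

The shipped lipid templates (LARG, SMAL, ANIO) and toy proteins are
synthetic: idealized bead geometries meant for testing and
demonstration, not a port of any published force-field library.  Real
Martini molecules can be imported from structure + topology files.

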