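# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## System and units

The system is a closed spherical DOPC bilayer (a liposome) in explicit
water with a dissolved noble-gas fraction. Coordinates are nanometres
internally everywhere; only the shape module reports in ångströms, the
customary unit of molecular-volume servers. Masses are unified-atomic-mass
united-atom values (CH, CH2, CH3 as single sites). Gas atoms are single
Lennard-Jones sites with the standard parameters He (ε = 0.084 kJ/mol,
σ = 0.256 nm), Ne (0.289, 0.278), Ar (0.979, 0.340), Xe (1.900, 0.406).

## Vesicle construction

A monolayer carrying N lipids at area per lipid *a* defines a headgroup
sphere of radius `R = sqrt(N·a / 4π)` (surface number density n = N/S).
Default areas are 0.95 nm² at the outer surface of the external monolayer
and 0.50 nm² at the inner surface of the internal monolayer; with the
study-sized counts 1188/495 these give R ≈ 9.48 / 4.44 nm. Whether a
reference density applies at the headgroup spheres or mid-monolayer is a
modelling choice; the spec of a build takes explicit per-surface areas, and
`VesicleSpec.from_reference_density` covers the equal-density reading.

Anchor points are a deterministic spherical Fibonacci lattice (quasi-uniform,
reproducible, no force relaxation — downstream analysis needs geometry, not
minimised packing). Each lipid is oriented along its local radial vector,
spun about its own axis by equally spaced angles, and optionally tilted.
A KD-tree clash check rejects builds in which heavy atoms of different
lipids come within 0.25 nm, naming the offending monolayer pair.

The united-atom DOPC template is idealised: planar zig-zag chains with
constant 0.153 nm C–C bonds and a 0.133 nm cis double bond between chain
carbons 9 and 10. The axial rise per carbon is 0.095 nm for the 18-carbon
default — the shorter effective length of fluid-phase chains; a fully
extended all-trans chain (rise 0.125 nm) cannot fit two opposing monolayers
between the radii above, and real DOPC tails are gauche-shortened to a
comparable degree. Short synthetic templates (< 14 carbons) use the exact
all-trans tetrahedral rise, which makes every C–H vector exactly
perpendicular to the chain axis — the property the order-parameter ground
truth exploits.

Solvation places SPC-geometry waters on a jittered cubic lattice excluding
the lipid-occupied radial band; dissolved gas replaces
`round(molar_fraction × molecule_total)` waters chosen uniformly at random
(seeded), or an explicit count when the two published conventions disagree.
Replacement indices are retained for provenance.

## Synthetic trajectories and their ground truth

The generator emulates the study system at reduced scale: 450/187 lipids
with 6-carbon all-trans tails in an 18 nm box by default, sized so the five
compartments are geometrically unambiguous relative to the 1.0 nm contact
cutoff. Gas atoms are resampled per frame uniformly within their assigned
compartment zone following a piecewise-linear occupancy schedule (counts by
largest-remainder rounding, so planted counts are integers that sum to the
gas total). Planted nanobubbles are hexagonal close packings at 1.05 σ
spacing — below the 1.5 σ linkage cutoff, so clustering must recover each
droplet as one component by design. Ground truth is recorded before noise.

Two constructions make the order-parameter truth closed-form. Lipid spins
about the molecular axis are equally spaced, so for C–H vectors at angle γ
to the chain axis tilted θ from the radial direction, the spherical-harmonic
addition theorem gives the leaflet average exactly:
`S = P2(cos θ) · P2(cos γ)` (γ = 90° for all-trans sp3 carbons, hence
S = −½·P2(cos θ)). Tilt directions alternate sign between neighbouring
lipids, cancelling the lateral centre-of-mass bias a uniform tilt would
create (P2 is even in θ, so the planted statistics are unchanged); this
keeps the measured radial director — phosphorus position relative to the
lipid centre of mass — aligned with the construction lattice to ~10⁻³ nm.

The expected probe volume of a planted droplet is its space-filling lattice
volume `N · s³/√2` (the probe envelope tracks the mid-surface of a close
packing, not its outermost atom shell); measured volumes land within ~5–10%
of this for droplet radii ≥ 1 nm at 0.5 Å grid. The applied sphericity of
an affine deformation is computed from the exact ellipsoid surface area
(incomplete elliptic integrals).

What the generator does **not** emulate: forces, diffusion, correlated
dynamics (atoms are resampled independently per frame), water structure
(lattice solvent at reduced density), membrane undulations, or lipid
exchange between leaflets. Passing the recovery tests therefore establishes
that the estimators measure what they claim on known geometry — not that
an MD trajectory would satisfy any particular value.

## Radial density profiles

Atom masses accumulate into half-open spherical shells `[r, r+Δ)` of width
0.2 nm (default) about the per-frame centre of mass of all lipid atoms;
density is frame-averaged shell mass over shell volume `(4π/3)[(r+Δ)³−r³]`
in kg/m³. Atoms beyond `r_max` go to an overflow tally so the mass ledger
always balances exactly; a *lipid* atom in the overflow is an error (the
vesicle must stay whole — no periodic unwrapping is attempted). The
interlayer minimum is the raw-density minimum between the innermost and
outermost prominent peaks (prominence ≥ 5% of the density range): the
headgroup spheres are the radially extreme lipid layers, and selecting
extreme rather than tallest peaks is robust to the spiky profiles rigid
templates produce. Ties break toward the smaller radius.

## Compartment classification

Five disjoint reference sets are resolved per frame: external and confined
water oxygens (split at the mean inner-headgroup radius), outer and inner
monolayer lipid heavy atoms, and — defining the interlayer gap — the
terminal carbons of each acyl chain. Leaflets are split by phosphorus
radius at the midpoint of the phosphorus radial range. Each gas atom joins
the domain of its nearest reference atom within the 1.0 nm cutoff
(minimum-image distances, KD-trees with periodic boxes); exact ties break
by the fixed priority gap > inner > outer > confined > bulk (most local
wins). Atoms with no reference in range fall back to a radial-zone
assignment using the mean headgroup and terminal-carbon radii, making the
classifier total. The implementation contract is bitwise agreement with an
exhaustive all-pairs classifier, enforced in tests over 1000 random frames.

## Probe volumetrics

The solvent-excluded envelope uses the roll-back construction in two
passes. The field `F(x) = max_i (r_i + r_probe − |x − a_i|)` is evaluated
exactly on the grid (KD-tree nearest-atom distances per radius group); its
zero level set, extracted sub-voxel by marching cubes, is the
probe-accessible boundary. Every grid point closer than one probe radius to
that boundary (distance to the triangulation vertices) is rolled away, and
a second marching-cubes pass at level `r_probe` triangulates the excluded
envelope; the mesh yields volume (signed tetrahedra) and area. This
two-pass level-set route replaces the more common pair of Euclidean
distance transforms because EDT distances are quantised to the voxel
lattice, which biases small-body surfaces by ~h/3 — too coarse for the
analytic fixtures (single sphere within 5%/2% at 0.5 Å).

Defaults: probe 1.4 Å (a water-sized probe), grid 0.5 Å, with a memory
guard that rejects grids above 6·10⁷ voxels; gas-phase rendering
conventionally uses a 6.0 Å probe. United-atom van-der-Waals radii:
C sites 1.88 Å, N 1.625 Å, O 1.48 Å, P 1.871 Å, gases σ/2. The surface is
the solvent-excluded envelope even where reports label the column
"accessible surface area", because the derived quantities reproduce from
that convention; normalisation against a control divides unrounded values
and refuses mismatched probe/grid settings.

The pipeline's shape stage defaults to 1.0 Å spacing (vesicle-sized grids
at 0.5 Å are memory-hungry); the library default stays 0.5 Å.

## Nanobubbles

A condensed gas fraction is a single-linkage connected component of one
species under pairwise distance ≤ 1.5 σ (about the first LJ coordination
shell; the droplet criterion is exposed as a parameter since no single
convention exists), containing at least 2 atoms ("larger than a single
water molecule" operationalised). A cluster's compartment is the majority
label of its members, ties to the more interior domain. Per-compartment
probe volumes are normalised by the external-bulk sum; a zero bulk sum
flags the normalised row undefined rather than dividing.

## Order parameters

For sp3 chain carbon C_i, the two pseudo-hydrogens lie in the plane through
C_i perpendicular to C_{i−1}→C_{i+1}, at ±half the tetrahedral angle about
the in-plane bisector; the scalar triple product
`det[C_{i−1}−C_i, C_{i+1}−C_i, H−C_i]` is positive for the Pro-S hydrogen
under the convention used here, so mirror-imaging a chain swaps the labels
(CIP-consistent). The sp2 pair of the cis double bond — detected
geometrically by its shortened bond (< 0.143 nm) — carries a single
in-plane bisector hydrogen used for both channels. Collinear chain segments
invalidate that lipid for the frame (logged and skipped).

`S_CD(k) = ⟨(3cos²θ − 1)/2⟩` accumulates separately for Pro-S and Pro-R
over the lipids of one leaflet and the frames of a window (default: the
last 20 ns). The default director is the laboratory z axis: on a sphere
this averages orientational order away, which matches the small magnitudes
reported for vesicles, but which convention a given analysis tool used is
often not stated — so the curvature-aware alternative (the lipid's
instantaneous radial unit vector, from its phosphorus position and the
vesicle centre of mass) is a first-class mode, and the tests assert the
magnitude ordering |S_lab| ≪ |S_radial| on radially ordered fixtures.
C1 (the ester carbonyl) is excluded; C2 through C_{n−1} are reported.
Leaflet assignment follows the headgroup phosphorus radius relative to the
interlayer density minimum, ties to the outer leaflet.

## Problem sizes

Tests run on the reduced 450/188-lipid vesicle (≈ 19 000 lipid atoms,
≈ 60 000 water atoms) with 2–5 frame trajectories, 60–80 gas atoms and
droplets of ≤ 250 atoms; the classifier oracle uses 1000 random 200-atom
frames. The builder is also exercised at the full 1683-lipid study scale
(90 882 atoms), which constructs in well under a second.

## Known limitations

- The builder produces idealised geometry, not equilibrated structure: no
  energy minimisation, no force fields, no topology files for MD engines.
- Rigid templates give spiky (layered) density profiles; peak magnitudes
  are the right scale (~1000 kg/m³ at the headgroups) but not smooth.
- The probe-volume mesh is a level-set approximation: interior cavities
  sealed off from the exterior are treated as excluded volume boundaries,
  not enumerated or classified.
- Normalised shape scores published at one- or two-decimal precision do not
  always round-trip exactly from other printed entries in the same row;
  reproduction is asserted to one unit in the last printed digit.
- The order-parameter director convention used by any external analysis
  must be known for quantitative comparison; lab-frame and radial values
  differ qualitatively on a sphere.
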