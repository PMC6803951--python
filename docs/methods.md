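# Methods

## Scope and model chain

The package computes, for single-walled carbon nanotubes (SWCNTs):
atomistic geometry (pristine / point-defected / finite), a π-band
tight-binding electronic structure, the Kubo–Greenwood optical
conductivity, thin-film absorption spectra at normal incidence, random
SWCNT networks with welding-relevant contacts and hot-spot maps, and
exact coarse-grained composition manifests. The welding dynamics itself
(reactive molecular dynamics) and the coarse-grained matrix/membrane
dynamics are deliberately out of scope: the package produces their inputs
(geometry + defects + temperature factors; bead manifests), not their
trajectories.

## Geometry

Tubes are ideal rolled-graphene cylinders: the sheet with lattice constant
a = 0.246 nm (a_cc = a/√3 = 0.142 nm) is wrapped along the chiral vector
C_h = n·a1 + m·a2 and repeated along the translation vector T, with
|T| = √3|C_h|/d_R, d_R = gcd(2n+m, 2m+n), and 4(n²+m²+nm)/d_R atoms per
period. Atoms live exactly on the cylinder of the analytic diameter; the
tube axis is z, coordinates are nm, indexing 0-based. Bonds come from a
global 0.17 nm distance cutoff (midway between first- and second-neighbour
shells), with axial periodic images.

No geometry optimization is applied: reproducible topology matters more
for a nearest-neighbour tight-binding model than sub-picometre coordinate
shifts, since the Hamiltonian depends only on the bond graph. An optional
harmonic nearest-neighbour relaxation pass (`relax_bonds`, steepest
descent, force tolerance 1e-4) exists for users who want bond lengths
equalized after defect surgery; it is OFF everywhere by default.

**Defects.** Single vacancies remove one atom and are left unreconstructed
(the dangling 2-coordinated neighbours are handled naturally by the
tight-binding model and are exactly the sites the hot-spot map targets).
Double vacancies remove a bonded pair (deterministically the lowest-index
neighbour when unspecified). Stone–Wales rotations turn the bond by 90°
about its midpoint in the local tangent plane and rebond with the global
cutoff; with ideal geometry the rotated bonds land at 1.065·a_cc, inside
the cutoff, and the four spurious former-neighbour distances at 1.69·a_cc,
outside — so the 5-7-7-5 topology emerges from the cutoff alone. Mixed
defects apply a list sequentially. Placing a defect within two bond
lengths of an existing one requires an explicit override (`allow_close`).

**Finite tubes** round the requested length DOWN to whole periods (never
exceeding the requested box) and phase the axial cut so each rim atom
loses exactly one bond, giving the clean 2-coordinated open edge; rims are
tagged as open-end sites. A cut at an arbitrary phase can strand
1-coordinated atoms (an artefact, not a physical edge), which the phase
scan avoids.

**Ring census.** Rings are the faces of the surface embedding, traced with
the rotation system induced by ordering each atom's bonds by angle in the
local tangent plane. This is exact for tube graphs — unlike shortest-cycle
enumeration, which misses Stone–Wales heptagons (their edges' shortest
cycles are the adjacent pentagons). The test suite cross-checks against
RDKit's independent SSSR perception.

## Electronic structure

Orthogonal nearest-neighbour π-orbital tight binding: on-site ε₀ = 0,
hopping γ₀ = 2.7 eV on every bond. This *replaces* a self-consistent
density-functional tight-binding Hamiltonian by design. What survives the
replacement: the metal/semiconductor dichotomy ((n−m) mod 3), van Hove
singularities and the 1/d gap scaling, selection rules, the qualitative
defect physics (new states, broken symmetries). What does not: absolute
transition energies and peak heights — film spectra are therefore treated
as property-level results, not value-matched predictions.

The Bloch Hamiltonian uses the atom gauge,
H_ij(k) = −γ₀ Σ_L exp(ik(z_j + L·P − z_i)), so eigenvalues equal the
zone-folded graphene dispersion exactly (verified to 1e-6 eV over the full
study set) and the axial momentum operator from ∂H/∂k agrees element-wise
with the commutator form (m_e/iħ)[z, H].

The chemical potential solves the half-filling count (one π electron per
carbon, spin 2 carried explicitly) by bracketed root finding to 1e-9 eV;
for bipartite (pristine or vacancy-defected) lattices it lands exactly at
ε₀, while Stone–Wales defects (odd rings) shift it.

**Minimal gaps** are found by continuous minimization over k (coarse
16-point scan + bounded refinement), because a fixed k-grid overestimates
the gap of metallic tubes whose Dirac point falls between grid points
(at Nk = 64 an armchair tube shows a spurious ~0.15 eV grid gap). Cells
above 600 atoms use sparse shift-invert diagonalization near ε₀.
Electronic temperature defaults to 300 K (the thermostat value 310 K used
for the coarse-grained systems is a different, classical temperature).

## Optical conductivity

The Kubo–Greenwood double band sum with resonance denominator
E_n−E_m+Ω+iη, occupation factor (f_n−f_m)/(E_n−E_m), prefactor
2e²ħ/(i m_e² S_cell), 1/N_k zone average, and P = (m_e/ħ)∇_k H. Numerical
choices:

* the intraband/degenerate 0/0 ratio is replaced by its analytic limit
  ∂f/∂E (pairs closer than 1e-9 eV); this is the standard regularization,
  yields the Drude-like response of metals, and its sign is fixed by
  passivity (Re σ ≥ 0, asserted as a property test);
* η defaults to 0.05 eV (no physical value is prescribed; spectra scale
  with it as usual for phenomenological broadening), temperature 300 K;
* perpendicular polarizations (and all directions of finite tubes) use the
  commutator matrix elements; **no depolarization correction** is applied,
  so perpendicular magnitudes are known upper bounds;
* degenerate subspaces enter only through Σ|P|², which is unitary
  invariant — eigenvector tie-breaking cannot affect σ (asserted by a
  random-remixing test);
* everything is evaluated in SI inside the kernel; the output sheet
  conductivity is in siemens so σZ₀ is dimensionless.

The kernel is validated against an independent pure-python pair sum to
1e-10 relative, against the two-level closed form (Lorentzian of width η
at the transition energy), and against supercell doubling (σ per area
invariant to 1e-6).

## Film absorption

A film much thinner than the wavelength is a current sheet between vacuum
half-spaces: R = −σZ₀/(2+σZ₀), T = 2/(2+σZ₀), A = 1−|R|²−|T|², Z₀ = 120π Ω.
A + |R|² + |T|² = 1 holds by construction; lossless (purely imaginary) σ
absorbs nothing; over real σ, A = 4x/(2+x)² with x = σZ₀ peaks at exactly
1/2 at x = 2 — the 50% single-sheet bound. No multilayer/transfer-matrix
stack is modelled; a thickness ≥ λ_min/10 triggers a validity warning.

S_cell, the film area per tube normalizing the sheet conductivity, is a
modelling choice the sheet formula needs but no first principle fixes:

* side-illuminated parallel-tube film: S_cell = period × (d + 0.5 nm),
  encoding the ~0.5 nm wall-to-wall raft spacing;
* end-illuminated open-end film: S_cell = (√3/2)(d + 0.5 nm)², the
  hexagonal-packing cross-section.

Analytics: peak finding with an absolute-prominence threshold (default
0.01 in A); peak counts per wavelength window (defaults 200–400, 650–800,
900–1150, 1800–2400 nm, left-closed [lo, hi)); A ≥ level intervals by
linear interpolation. Wavelength grids are uniform in photon energy,
10–3000 nm for periodic-tube films and 100–3000 nm for the ~40 nm-thick
open-end film.

## Networks

Tubes are rigid straight cylinders (5–20 nm lengths are far below
persistence lengths), placed by random sequential insertion: uniform base
point, uniform orientation on the sphere, uniform length in range (snapped
down to whole periods so segment geometry and atomistics agree exactly),
rejected when any surface–surface distance to a placed tube is below the
0.34 nm van der Waals exclusion. Distances are closed-form segment–segment
closest approaches minus the radii, under the minimum-image convention
(all 27 periodic images checked explicitly). Packing failure raises an
error carrying the number placed.

Contacts are tube pairs with surface gap in [0.2, 0.4] nm — the range
where welding initiates. Detection uses a conservative spatial grid to
prune pairs, followed by the exact distance check; the result is proven
equal to the brute-force all-pairs scan in the tests. Per contact, one
defect (kind drawn uniformly from the configured set) is applied to each
partner tube at the nearest atom; consumed atoms are skipped with a
warning. The hot-spot map assigns defect-site and open-rim atoms a
temperature factor 1 + U(0.16, 0.20) — defective regions absorb more and
conduct heat worse — and exports it through the PDB B-factor column as the
hand-off to reactive-MD welding codes.

Density is N·m_C/V (m_C = 12.011 × 1.66054e-27 kg), exact and intensive.
At the reference scale (258 tubes of 5–20 nm in 65×45×40 nm) the packed
atom count is seed-dependent at roughly 190–210k and the density ~30–35
kg/m³; note that a printed density of 60 kg/m³ for a similar box is about
twice what its own printed atom count implies — the package reports the
computed value and does not tune to either number.

## Coarse-grained manifests

Exact integer bookkeeping only (no coordinates, no dynamics): components
as (name, beads per molecule, molecule count), grand totals, a declared-
total consistency check, JSON round trip. The DPPC lipid maps to 12 beads
(2 head + 2 glycerol + 2×4 tail), which exactly reconciles the membrane's
8,450 molecules with its 101,400 beads. Thermostat metadata defaults to
310 K. The chitosan box has no published grand total; its manifest derives
one (229,064) from the component counts without asserting it externally.

## Synthetic data and what the tests show

There is no external dataset; the geometry and network builders *are* the
data generators, and their defaults are the study conditions (16
chiralities, 0.6–2 nm diameters, 1V/2V/SW/mixed defects, ~40 nm open
tubes, 258-tube 65×45×40 nm box, 0.2–0.4 nm contacts, 16–20% overheat).
They emulate ideal structures: no geometry relaxation, no curvature
corrections to hopping, no tube bending or entanglement, no vacancy
reconstruction. Passing tests therefore certify the lattice bookkeeping,
the kernels and their analytic identities — not quantitative agreement
with measured or self-consistently computed spectra of real, relaxed,
interacting tubes.

Problem sizes in the default test run are chosen at desk scale: dense
diagonalization for cells ≤ a few hundred atoms, sparse residual/
shift-invert techniques for the 1324- and 2812-atom cells, Nk between 4
and 64 per test, 50-tube networks for the exact contact-equality checks,
and one 258-tube packing.

## Known limitations

Zone-folding tight binding misses curvature-induced σ–π hybridization
(small-diameter armchair tubes stay exactly metallic here), excitons
(dominant in real optical spectra), and electron–phonon broadening (η is
phenomenological). Perpendicular absorption lacks the depolarization
suppression. Vacancies are unreconstructed. Networks contain straight
tubes only. The current-sheet film model ignores substrate and multiple
reflections. These are the package's documented trade-offs for exactness
and reproducibility of everything it does compute.
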