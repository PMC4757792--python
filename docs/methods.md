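# Methods

This note documents the models behind `conchtough`: their assumptions, the
defaults and why they were chosen, the numerical machinery, and what the
synthetic-data-driven tests do and do not demonstrate about real materials.

## 1. Coarse-grained lattice fracture

### Medium and bond law

The solid is a two-dimensional triangular network of central-force springs:
nodes on staggered rows `sqrt(3)/2` apart (in units of the rest length),
six nearest neighbours per interior node. Each bond is linear-elastic up to
an abrupt, irreversible break at a critical stretch `e_c` (dimensionless
strain). This is the simplest brittle lattice model; a perfect triangular
network of such springs is elastically isotropic with 2D Young's modulus
`E_2D = 2k/sqrt(3)` and Poisson ratio 1/3 (`k` = spring constant), which the
test suite verifies by convergence of the measured uniaxial stiffness.

Internally the lattice is nondimensional (`spacing = 1`, `k = 1`) for
conditioning and clarity; physical units enter only at reporting through the
`LatticeSpec` fields (spacing in nm, stiffness in N/m, thickness in nm).
Work of fracture is therefore exact in the ratios that matter (enhancement
factors) and carries units only through a single conversion.

Defaults: `spacing = 25 nm` (a 200 nm nanocrack spans 8 bonds — enough to
resolve each crack while keeping a full two-orientation sweep under a
minute), `e_c = 0.04` (a brittle, ceramic-like failure strain; enhancement
ratios are independent of `e_c` because the problem is linear up to each
break), `thickness = 100 nm` (TEM-lamella-like normalisation; cancels in
ratios).

### Loading and boundary conditions

Mode I: the top and bottom node rows are pulled apart by a prescribed
vertical displacement. Grips are rollers — vertical components prescribed,
horizontal free — with a single pinned horizontal component to remove the
rigid translation; prescribing both rows kills the rotation. Rollers rather
than clamps so that the same boundary conditions measure a true uniaxial
modulus on intact samples. Lateral boundaries are free.

### Quasi-static algorithm

Because the response is linear at fixed bond topology, the whole field at
grip opening `U` is `U` times the unit-opening solution. The trajectory is
therefore integrated **event by event**:

1. solve once at unit opening; compute every tensile bond strain
   `e_b` per unit opening;
2. the next event is at `U* = min_b e_c / e_b`; if some bond already
   exceeds `e_c` at the current opening (a cascade after a previous break),
   it breaks at fixed `U` instead;
3. break exactly one bond per event — the largest stretch ratio, ties to
   the lowest bond index — and re-equilibrate at fixed opening;
4. stop at separation or at a documented maximum opening (default: eight
   times the opening at which an intact strip reaches `e_c`).

Separation is detected two ways: the grips fall into different graph
components, or the grip-to-grip stiffness drops below `1e-9` of its initial
value (a dangling hinge chain can stay formally connected while carrying no
load).

Removing one bond is a rank-one stiffness update, so the per-event re-solves
reuse one sparse Cholesky-like factorisation (SuperLU) through a
Sherman–Morrison–Woodbury correction, re-factorising every 50 events. A
`1e-9·k` Tikhonov term keeps the reduced system positive definite when bond
removal creates floating fragments; such fragments carry no load and thus do
not contribute to the energy bookkeeping. The event sequence is verified
bond-for-bond against a dense-matrix brute-force re-implementation on small
lattices.

### Energy bookkeeping

At fixed topology the stored energy is `U² φ` with `φ` the unit-opening
energy, so the boundary work over a loading segment is `φ (U₂² − U₁²)`
exactly, and the energy dissipated by an event at fixed `U` is the drop in
stored energy, which is bounded below by the broken bond's own energy
(removing a constraint at fixed displacement can only release additional
relaxation energy). Work = stored + dissipated holds to machine precision
by construction and is re-verified to 1e-6 relative by an independent dense
replay in the tests.

**Toughness.** Work of fracture = cumulative dissipated energy ÷ (projected
primary-crack advance × thickness); the peak boundary force ÷ (width ×
thickness) is reported alongside as a critical stress. The enhancement
factor of a patterned sample is its work of fracture over the homogeneous
baseline's; the empty pattern gives exactly 1 by construction.

### Nanocrack pattern geometry

Cracks are straight segments carved by deleting every bond they properly
cross (strict interior crossing; touching at an endpoint does not cut, and
all crack coordinates are nudged 0.26 of a spacing off the node lattice so
no segment passes through a node or along a bond). Carving is validated
against an independent `shapely` crossing oracle.

The array is treated as a **material microstructure**: it tiles the whole
specimen interior, keeping at least 10 spacings from every free boundary to
suppress image effects. Conventions, chosen on physical grounds and frozen:

* *y*-nanocracks (perpendicular to the primary crack): vertical segments in
  columns a period `s` apart along x; in-column pitch `2a + d` (`d` =
  tip-to-tip ligament). Even columns have one crack straddling the main
  crack plane (the blocking configuration found ahead of arrested tips);
  odd columns are offset by half a pitch, so the plane passes through a
  shielded gap — a staggered arrangement like the observed patterns. The
  array phase is anchored at the tip (nearest column `s/2` ahead), which
  keeps the tip-to-pattern distance comparable across a period sweep
  instead of varying with the commensurability of `s` and the domain.
* *x*-nanocracks (parallel): horizontal segments in rows at `±s/2, ±3s/2…`
  off the crack plane (rows *on* the plane would merely pre-extend the main
  crack), collinear pitch `2a + d` along x.

Alternative conventions (aligned columns, tip-local patches, margin-anchored
phase) were evaluated; the frozen one is the only one in which **both**
orientations toughen across the whole grid — i.e. the shielding property
holds — and in which trends are monotone and robust to doubling the
resolution.

### Default study conditions and observed behaviour

Lattice 110 × 76 nodes (2.7 µm × 1.6 µm at 25 nm spacing), primary crack
750 nm, pattern geometry 2a = 200 nm, d = 200 nm, s ∈ {300…1000} nm, no
jitter. At these conditions the package computes enhancement factors of
1.57–2.27 for the *y*-family (maximal for the densest array, s/2a = 1.5,
with s/2a = 2.0 within 4%) and 1.05–1.64 for the *x*-family, decaying
toward 1 in the dilute limit; *x*-patterns also cut the effective modulus
by up to ~29% while *y*-patterns cost only ~2%, consistent with cracks
parallel to the load plane carrying most of the compliance.

**Known limitations.** (i) With linear springs and an abrupt break, the
*y*-family's toughness is nearly flat in `s` at fine resolution for
s/2a ≤ 2.5 — the model contains no mechanism (e.g. nonlinear nanocrack
coalescence) that penalises very dense arrays, so the optimum sits at the
dense end of the grid rather than strictly inside it. (ii) Isolated
off-plane parallel cracks shield only weakly, so the dilute *x*-tail drops
to a few percent of enhancement. Both are properties of this bond law and
metric, not numerical artifacts; they are stated here because stronger
claims (a sharp interior optimum, a uniform ≥ 1.3 floor) have been reported
for related models with different, unpublished discretisations.

## 2. Plane-elastic FEM: δ5 and the domain-integral J

Single-edge-notch rectangle, width `W` along x, height `H` along y, sharp
crack along `y = H/2` from the left edge to `x = a`, modelled with
duplicated crack-face nodes (the notch root radius is a config input; the
default is an ideally sharp slit). Elements are linear (constant-strain)
triangles on a structured grid geometrically graded toward the tip: each
refinement level halves the two intervals adjacent to the tip, so `r`
levels shrink the tip spacing by `2^r`. No singular elements — the domain
integral does not need them at the documented refinement.

Material: homogeneous isotropic elasticity, aragonite defaults E = 120 GPa,
ν = 0.3. **Plane strain by default** with a plane-stress switch: thin TEM
lamellae argue for plane stress, but plane strain is the conservative
fracture convention; the choice only rescales J by `(1 − ν²)` and cancels in
the nanotwinned/single-crystal contrast.

Loading is an opening grip displacement (top edge `+Δ/2`, bottom `−Δ/2`,
horizontal free, one pinned node). A separate remote-uniform-tension mode
(trapezoidal nodal lumping of the edge traction) exists because handbook
stress-intensity solutions for edge-cracked strips assume free remote
tension; under displacement grips the suppressed specimen rotation roughly
halves J at a/W = 0.4, which is physics, not error.

* **δ5**: vertical relative displacement of two gauge points at
  `(a₀, H/2 ± g/2)`, straddling the *original* tip; `g` defaults to 5% of
  the specimen width (the classical fixed millimetre gauge cannot apply at
  nanoscale; the default keeps the gauge well inside the K-dominant zone).
  Interpolation is barycentric in the containing element.
* **J**: equivalent domain integral
  `J = ∫_A [σ_ij ∂u_i/∂x − W δ_1j] ∂q/∂x_j dA` with a conical weight `q`
  (1 inside r₁, 0 outside r₂, linear between). Per-element constant fields
  make the integral a single vectorised sum. Validation: path independence
  across three annuli to < 2%; agreement with the Gross–Brown single-edge-
  notch K formula (`J = K²/E'`) to < 5% at the documented mesh (48 × 64
  coarse grid, refinement 6), converging monotonically from below; and
  agreement with an independent finite-difference energy-release
  computation under grip loading.
* **CTOD matching**: for each measured `(Δa, δ5*)` pair the crack is
  extended to `a₀ + Δa`, one unit-opening solve gives `δ5_unit` and
  `J_unit`, and linearity gives the matched load exactly:
  `λ = δ5*/δ5_unit`, `J = λ² J_unit`. Units: GPa·nm ≡ J/m², so J is
  reported directly in J/m².

## 3. Self-similar hierarchical composite

Each level is a staggered arrangement of hard platelets (the composite one
level below) in a thin organic matrix; platelets carry tension, the organic
transfers shear. Level 0 is the mineral building block. The bottom-up
design step, with `φ` the level's mineral fraction, `G, τ` the organic
shear modulus and shear strength:

* platelet thickness = flaw-tolerance size of the lower-level material,
  `h = α Γ E / S²` with `α = 1` (Griffith estimate for a platelet-spanning
  crack; order-unity prefactors shift absolute values, not ratios);
* aspect ratio from the equal-strength condition `ρ = S/τ` (shear transfer
  just saturates the platelet strength); an override exists for
  fixed-geometry studies;
* modulus: series (tension-shear-chain) formula
  `1/E' = 4(1−φ)/(G φ² ρ²) + 1/(φ E)`; always below the Voigt bound `φE`;
* strength: `S' = (φ/2)·min(ρτ, S)` — the factor 1/2 is the mean-to-peak
  platelet stress ratio of the linear transfer profile; the governing
  branch is recorded;
* fracture energy: organic shear work over the pull-out volume. Default
  regime `pullout` assumes the interface shear resistance persists through
  complete platelet pull-out (mineral-bridge/asperity friction picture):
  per unit crack area `Γ' = φ τ ρ² h / 4`. The alternative
  `strain_limited` regime stops sliding at the organic failure strain:
  `Γ' = τ γ_f (1−φ) ρ h`.

Defaults: mineral E = 100 GPa, S = E/30 ≈ 3.3 GPa (flaw-free nanoscale
strength), Γ = 1 J/m²; organic G = 1.0 GPa, τ = 0.04 GPa (protein-layer
stiffness and interface shear strength of the magnitude reported for
biogenic aragonite composites), γ_f = 10. Baseline: 3 levels, per-level
`φ = 0.99^(1/2)` so the total mineral content is ≈ 99 wt%.

Substituting the design rules into the pull-out formula gives
`Γ_{n+1} = (α φ / 4τ) E_n Γ_n`: toughness grows by a factor `∝ E_n/τ`
per level — the exponential-with-levels property — and the growth factor is
nearly level-independent when the shear compliance term is small (tested).

**Sensitivity to the lowest level.** Scaling level-0 toughness *and*
strength by `c` rescales `ρ ∝ c` and `h ∝ 1/c`, so the dissipation term's
explicit `S`-dependence cancels and the overall toughness responds as
`c × (product of modulus-recovery ratios E_n(c)/E_n(1))`. The response is
therefore strictly super-linear but close to `c` unless the organic shear
compliance dominates the level stiffness. With the defaults the three-level
amplification at c = 3 is ≈ 3.0; a parameter scan shows it exceeds 10 only
for interface shear strengths ≥ 0.5 GPa, outside the defensible range —
and in a regime where the model's total amplification is inconsistent with
the ~10³ known for real conch-like materials. Reports of order-of-magnitude
amplification for such hierarchies therefore require physics beyond this
recursion (plausibly multi-level process-zone dissipation); this
implementation states the recursion it actually computes.

The inverse problem — recover the level-0 fracture energy from an overall
toughness — is a bracketed 1D root find (Brent) on the strictly increasing
forward map; recovery is tested to 1e-6.

## 4. Synthetic inputs

* **CTOD curves**: parametric means, nanotwinned
  `δ5(x) = 50 nm · (1 − e^{−x/150 nm})` (concave, saturating — a blunting
  tip) and single-crystal `δ5(x) = 0.012·x` (shallow, near-linear — a sharp
  brittle tip); the nanotwinned mean is strictly above the single-crystal
  mean at every extension, and the ~10× contrast in saturated opening maps
  through the quadratic CTOD→J relation to a ~100× J contrast. Noise is
  additive Gaussian, clipped at zero, fully seeded. Only monotonicity and
  the class ordering are claimed as faithful to measured curves; the
  parametric forms are conveniences.
* **Pattern grids**: one pattern per period with the observed geometry
  (2a = d = 200 nm); optional uniform positional jitter, drawn from the
  run's seeded generator.
* **Fixture lattices**: ≤ 20 × 20 deterministic lattices (intact, notched,
  patterned) for tests.

Passing tests on these inputs demonstrate internal correctness (oracle
agreement, conservation laws, scaling identities, reproducibility) — not
that the bond law, the parametric CTOD forms, or the recursion defaults
quantitatively describe any particular shell.

## 5. Determinism and problem sizes

All randomness (jitter, CTOD noise) flows through per-stage
`numpy.random.Generator` instances derived from one integer seed; ideal
geometry (`jitter = 0`, `noise_sd = 0`) is the default and fully
deterministic. The end-to-end pipeline records config, seed and SHA-256
checksums of every artifact in a manifest; re-runs reproduce checksums bit
for bit.

Problem sizes were chosen so the full default study — 17 lattice fracture
runs (8360 nodes each), two CTOD→J curves and the hierarchy sweep —
completes in well under a minute on one core; doubling the lattice
resolution (tested for the dense third of the period grid) changes
enhancement factors by < 5% and none of the qualitative statements above.
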