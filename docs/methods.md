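# Methods

## Model overview

A removable complete denture base is modelled as a linear-elastic,
isotropic, homogeneous solid in static equilibrium (mm–N–MPa units,
isothermal, no dynamics). Two materials are carried per element label:
the base acrylic (E = 1000 MPa) and the harder tooth acrylic
(E = 2000 MPa), both with ν = 0.3 and ρ = 1000 kg/m³ (density is carried
but unused in statics). Teeth are bonded to the plate node-to-node
(ideal adhesion — the dentition is chemically bonded in manufacture), so
there is no contact interface anywhere in the model.

The denture has no kinematic fixation: it floats on mucosa. The mucosa is a
segmented Winkler foundation — surface tractions proportional and opposite
to local displacement:

* **Intaglio segments** (four per side along the arch, on a band at the
  ridge crest): normal stiffness k_n (MPa/mm). The crest is where mucosal
  compliance is lowest, hence where the functional load is compensated;
  the remaining intaglio is soft mucosa and is left traction-free.
* **Border seal** (peripheral band of the intaglio): normal stiffness.
* **Retention zones** (two posterior intaglio ellipses): tangential
  stiffness only — friction-like holding forces opposing sliding.

An optional linear compliance law c(u_n) = 1/k₀ + c₁·u_n (penetration
positive) represents tissue stiffening as fluid is squeezed from the
contact zone; c₁ < 0 stiffens under load. It is solved by a secant
fixed-point iteration (re-assemble the foundation from facet-averaged
penetrations, cap 5 iterations). The default c₁ = 0 keeps the solve linear,
matching the single linear solve the analysis is built around.

## Geometry generator

The generator emulates a scanned mandibular denture with a parametric
construction: an elliptical arch centerline (width 50 mm, depth 45 mm,
sweep 200°) swept with a cross-section (width 12 mm) consisting of a ridge
saddle (height 4 mm), flanges dropping 5 mm at the rims and a plate
thickness of 3 mm above the crest. Tooth blocks are vertical prisms
(height 8 mm, band width 8 mm) whose arc extents realise the per-side
occlusal footprints {I: 60, II: 25, III: 50, IV: 100} mm², sized so
single-block pressures at 100 N span the physiological few-MPa range.
Frenal "cutouts for strands" are V-notches in the vestibular flange border
(vertical depth 4 mm ≈ 80 % of the flange height, arc width 4 mm, tapering
to a tip) at the midline and at the canine–premolar interstice on each
side — these are the classic stress-concentration sites of acrylic bases.

Values not fixed by published data (arch dimensions, cross-section,
support-band and notch sizes) were chosen once as anatomically plausible
for an average adult mandible and are all exposed as `ArchParameters`.

Meshing is a structured grid in (arc, cross, height) coordinates, each hex
split into six tetrahedra along a common diagonal (conforming across
cells). Hexes are generated for the right half and mirrored node-by-node
onto the left, so both the node set **and the tetrahedral decomposition**
are exactly midsagittally symmetric — symmetric loads then give discretely
mirror-symmetric stress fields, which is also the basis of the symmetry
tests. Tooth-arrangement variants displace or incline block nodes with a
weight growing linearly from the plate top to the occlusal surface, keeping
the bonded interface conforming while the occlusal centroid receives the
full requested transformation. Element order 2 (10-node tetrahedra) is the
default; order 1 is used for fast tests and demos.

## FEM details

Tet4 elements use constant-strain closed forms; tet10 elements use the
4-point Keast rule (exact for the quadratic-shape stiffness integrand on
straight-sided tets). Foundation terms integrate consistent surface mass
matrices (tri3/tri6) times the direction operator k_n n nᵀ + k_t (I − n nᵀ)
with outward facet normals. Occlusal loading applies a vertical traction of
magnitude P·|n_z| with P = F/S₀ (S₀ the horizontal projection of the
patch), so the integrated vertical force equals the prescribed force
exactly regardless of occlusal curvature. The solver is a direct sparse LU
(fixed COLAMD ordering, deterministic) with a 1e-8 relative-residual check;
a model with no foundation and no Dirichlet data raises an explicit
"unconstrained" error instead of failing in the factorization.

Stresses are evaluated per element at its nodes (constant for tet4, linear
for straight tet10) and averaged to mesh nodes with element-volume weights;
summaries report both the nodal-averaged and raw-element maxima, with the
nodal-averaged value as the default (smoother and the conventional choice
for contour maps). Equilibrium (foundation reactions = applied load) holds
to solver precision and is asserted at 0.1 % on every pipeline solve.

## Balance calibration

Because nothing pins the denture, an unbalanced foundation lets the uniform
all-teeth load pitch (anteroposterior tilt) or roll (lateral tilt) the base
as a quasi-rigid body, polluting the strain analysis. Calibration fits one
stiffness multiplier per segment pair (4 values, sides tied by symmetry,
bounded 10⁻²–10² in log space) with a deterministic trust-region
least-squares on the (pitch, roll) residual, each evaluation being one
linear solve; if the vertical displacement range then still exceeds the
0.02 mm target, the whole foundation is scaled up by doublings (angles
scale down proportionally, so no re-fit is needed). Rigid motion is
measured by a least-squares fit u ≈ t + ω × r over the base nodes. The
default k_n = 10 MPa/mm was chosen so that 100 N over the ≈2000 mm² of
supported surface settles ≈0.01 mm, inside the target band before
calibration even starts.

## Fatigue mapping

High-cycle life uses the S–N (Basquin) law σ_eq = σ_f + σ_L·N^(−β)
anchored at the yield point for N = 10³ cycles, giving
σ_L = 10^(3β)(σ₀.₂ − σ_f); below σ_f life is capped at N_max = 10⁹ cycles
(more chewing cycles than a human lifetime). The default criterion is
Smith–Watson–Topper, σ_SWT = √(⟨σ1max⟩₊·Δσ1/2), whose Macaulay bracket
makes purely compressive states incapable of opening-mode cracking; its
Basquin-side constants default to the uniaxial set (σ̃_u = σ_f, σ_V = σ_L,
β_VH = β), which makes the SWT curve coincide with the S–N curve under
fully reversed uniaxial cycling. The grouping of the SWT left-hand side is
isolated in `swt_equivalent`, so an alternative reading of the criterion is
a one-function change.

The default cycle model is *pulsating* (each mastication event applies and
removes the maximum-effort load, Δσ1 = σ1max); *fully-reversed* is provided
for sensitivity studies. Cycles convert to years with
years = N / (meals_per_day · chews_per_meal · 365); the default
3 × 1000 schedule makes ≈1.1×10⁶ cycles one year of service.

**Fatigue constants are placeholders.** No standardised constants exist for
denture acrylics; the defaults tie the yield point to the 60 MPa ultimate
compressive strength of the base resin, set σ_f = 0.4·σ₀.₂ (degradation is
observed from roughly 40 % of the static strength) and β = 0.1. They are
flagged (`placeholder=True`) in every report; quantitative service-life
statements require user-supplied constants via
`FatigueParams(...).confirmed()`.

## Problem sizes and verification scope

Default runs use the 2 mm tet10 mesh (~20 k nodes); tests and demo runs use
2–3 mm tet4 meshes (1–3 k nodes) so the full suite solves dozens of FEM
problems in minutes. Verification rests on closed forms and independent
oracles: uniform-stress patch tests (exact to 1e-9), a slender cantilever
against beam theory (2 %), single-element stiffness against numerically
differentiated shape functions (1e-9), Winkler closed forms, projection
and area formulas on spheres, and inverse-function round trips of both
fatigue curves.

## What the synthetic geometry does and does not show

The generator reproduces the *structure* of a denture-base analysis —
labeled functional regions, segmented compliance, block loading, balance,
concentrator notches — so pipeline behaviour (equilibrium, symmetry,
asymmetric-vs-symmetric ordering, life monotonicity, variant ranking)
transfers to real geometries. Absolute stress levels do not: a scanned
base is a thin shell with deep notches and an anterior cantilever, giving
roughly an order of magnitude higher anterior stress amplification than
this chunky parametric stand-in. In particular, on the default geometry
the maximum base stress tracks the applied block pressure closely, so the
incisor block (largest anterior footprint, lowest anterior pressure) does
not dominate the posterior blocks the way it does on patient geometry, and
at 100 N all predicted lives sit at the 10⁹-cycle cap. Comparisons between
arrangements remain meaningful because they share the same geometry.

## Known limitations

* Bilateral (tension-carrying) foundation springs; no unilateral contact.
* Retention modelled as linear tangential springs, not Coulomb friction.
* No crack propagation or damage accumulation; constant-amplitude loading
  only (no rainflow counting).
* Mandibular geometry only; the maxillary (torus-supported) case would
  need a different support layout.
* Gmsh interchange uses the MSH 2.2 ASCII dialect (physical groups carry
  patch labels); tet10 midside ordering follows the VTK convention.
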