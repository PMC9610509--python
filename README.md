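# rcdlife

Stress and fatigue service-life analysis of **removable complete denture
(RCD) bases**: the pink acrylic plates that carry artificial teeth on an
edentulous (toothless) mandible. Denture bases fail predominantly by
fatigue — a crack nucleates at a stress concentration (often the frenal
cutout notches or the midline) after months of chewing cycles — and the
choice of tooth arrangement strongly influences how long that takes. This
package is for biomechanics and prosthodontics researchers who want a
scriptable, reproducible pipeline for exploring those effects.

## What it computes

1. **Parametric geometry** (`rcdlife.geometry`): a mirror-symmetric
   horseshoe denture base with an alveolar-ridge saddle, four tooth blocks
   per side (incisors I, canines II, premolars III, molars IV), frenal
   cutout notches, a border-seal band, posterior retention zones and four
   mucosal support segments per side, meshed into 4- or 10-node tetrahedra.
   Tooth-arrangement variants (block displacement / inclination) are
   parameters.
2. **Linear elasticity** (`rcdlife.fem`): small-strain isotropic FEM on the
   labeled mesh with Robin (Winkler elastic-foundation) boundary terms for
   the mucosa, direct sparse solution, von Mises / principal stress
   recovery with nodal averaging. Unit system mm–N–MPa.
3. **Occlusal loading and balance** (`rcdlife.loading`): block pressures
   `P_k = F0 / S_k` from occlusal areas (default total force
   F0 = 100 N, the average jaw-closing force), symmetric / asymmetric /
   uniform load cases whose vertical resultant equals F0 exactly, a
   least-squares rigid-motion monitor (pitch / roll / yaw), and a
   calibration that tunes the per-segment mucosa stiffnesses until the
   uniform all-teeth load produces negligible tilt and a vertical
   displacement range within 0.02 mm.
4. **Fatigue life** (`rcdlife.fatigue`): the Basquin S–N curve
   `σ_eq = σ_f + σ_L N^(−β)` anchored so stress equals the yield point at
   10³ cycles (`σ_L = 10^{3β}(σ_0.2 − σ_f)`), and the Smith–Watson–Topper
   criterion `σ_SWT = √(⟨σ1_max⟩₊ · Δσ1 / 2)` for opening-mode cracking;
   nodewise cycles-to-failure maps capped at 10⁹ cycles, hazard classes
   (red ≤ 10³ cycles), and conversion to years of service via a
   mastication schedule (3 meals × 1000 chews per day by default).
5. **Scenario pipeline** (`rcdlife.pipeline`, CLI `rcdlife`): run the eight
   canonical load cases (blocks I–IV × symmetric/asymmetric), compare
   arrangement variants, and write VTK fields, JSON summaries and a
   max-stress CSV table.

## Worked example

```bash
python examples/02_static_stress.py
```

prints (default geometry, right-canine bite at 100 N):

```
case II:asymmetric-right: max von Mises 4.157 MPa (base nodes only: 2.577)
reactions [   0.   -0. -100.] N vs applied [   0.    0. -100.] N
rigid motion: pitch -0.0467 deg, roll 0.0288 deg, yaw -0.00652 deg
```

The foundation reactions balance the applied 100 N exactly (the built-in
equilibrium check); one-sided chewing tilts the denture slightly (pitch and
roll) while the vertical load produces no meaningful yaw. The maximum von
Mises stress in the base, 2.6 MPa here, is what the fatigue mapping converts
into a cycles-to-failure estimate. `examples/03_fatigue_life.py` shows the
fatigue side: a 40 MPa equivalent stress maps to 3.3×10⁶ cycles ≈ 3 years
of normal mastication, and fully compressed nodes can never initiate an
opening-mode crack. `examples/04_compare_arrangements.py` compares normal,
displaced and inclined tooth arrangements.

A thin CLI wraps the same pipeline:

```bash
rcdlife demo --outdir demo_results
rcdlife generate --out denture.msh
rcdlife calibrate --out calibration.json
```

## Scope notes

The geometry is a parametric stand-in, not a patient scan; absolute stress
magnitudes are geometry specific. The acrylic fatigue constants shipped as
defaults are documented placeholders tied to the 60 MPa ultimate
compressive strength of the base resin — supply measured constants
(`FatigueParams(...).confirmed()`) for quantitative service-life claims.
Crack propagation, plasticity, contact friction and thermal effects are out
of scope; see `docs/methods.md` for the model assumptions and numerical
choices.
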