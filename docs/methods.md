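# Methods

## Model

Four scalar fields evolve on a regular 2-D grid: an autocatalytic activator
A, a fast-diffusing inhibitor H, a consumable substrate S and a cytoskeleton
marker Y:

    dA/dt = c A²S/H − μA + (ρ_A + δ_A) Y + D_A ∇²A
    dH/dt = c A²S   − νH + (ρ_H + δ_H) Y + D_H ∇²H
    dS/dt = c₀ − γS − εYS                + D_S ∇²S
    dY/dt = dA − eY + Y²/(1 + fY²)

All quantities are dimensionless.  The activator catalyses itself and the
inhibitor (rate c, boosted by substrate); both degrade (μ, ν) and are
produced by differentiated cytoskeleton (ρ_A, ρ_H) plus the additive
*exogenous* supplies δ_A and δ_H, which model externally applied substances.
Substrate is produced by the neuron (c₀), degrades (γ) and is consumed by
cytoskeleton synthesis (ε, interpreted as neuron activity).  The Y equation
is a bistable switch: cells with transient activator exposure above a
threshold latch to Y ≈ 1 (at f = 10, e = 0.1 the on-state persists at
Y ≈ 0.89 even if A later vanishes), so the Y ≥ 0.5 set is the cell
silhouette and records the growth history.  Lateral inhibition requires
D_H ≫ D_A; the default coefficients come from the per-figure presets
(`spinepattern.params.preset`).

## Numerics

* Explicit forward Euler, 5-point Laplacian, zero-flux (mirror) boundaries;
  dx = 0.3, dt = 0.05, safely below the stability bound dx²/(4 D_H) ≈ 0.0865.
  A closed domain is the standard morphogenesis assumption; the integration
  scheme is the common choice for this model family.
* The stepping loop is compiled (numba) and performs per cell exactly the
  arithmetic of the reference `step_euler`/`reaction_rhs`/`laplacian` path;
  a test asserts bit-for-bit agreement between the two routes.
* H is floored at 1e-6 inside the A-equation denominator only (background
  H₀ = 0.001 makes raw division fragile).  Negative values after a step are
  clamped to zero and counted; for all presets the counter stays at zero.
* Degenerate inputs: non-finite fields raise immediately, naming the field
  and step; schedules violating the CFL bound are rejected at validation.

## Protocols

**Seeds.** Both protocols start from a 5-wide × 10-tall rectangle of
"black-region" values (A=2, H=0.02, S=1, Y=1) flush with the bottom
boundary, in a background of "white-region" values (A=0.001, H=0.001, S=1,
Y=0).  The seed must be narrower than the inhibitor's lateral range
(√(D_H/ν) ≈ 2.5 length units ≈ 8.5 px): a wide seed splits the activator
peak to its two corners and grows two diverging filaments instead of one
spine.  With the narrow seed a single peak sits at the tip and the seed
grows upward.

**Single spine.** 100×100 grid, t_end = 700 (14 000 steps).  The horizon is
calibrated so the slowest-growing spine (ε = 0.01, the mushroom) has formed
and stalled while the fastest (thin) spines have not yet sprouted secondary
laterals or reached the far boundary; all sweep comparisons use this same
schedule, so relative results are well defined.  No noise is used — the
protocol is fully deterministic.

**Dendrite.** 150×200 (rows × cols) grid.  Stage 1 grows a trunk under the
trunk preset for t = 40 000 (800 000 steps), by which time the tip has
reached the far boundary and stalled — important because a free tip would
itself branch during stage 2 and contaminate the spine count.  Stage 2
restarts from the trunk under the spine preset for the condition under
study, with a one-off uniform perturbation (amplitude 0.01, seeded) that
breaks the artificial left–right mirror symmetry of the deterministic
protocol.

## Morphometry

The silhouette is Y ≥ 0.5 (Y is bimodal near 0/1, so the midpoint is
robust).  Only the newborn part — rows above the seed or trunk — is
measured.  From the per-row width profile:

* h = number of occupied newborn rows × dx;
* w_head = maximum width of the newborn profile (the head of a spine is its
  widest part; the distal fraction searched is configurable);
* w_neck = minimum width between the head row and the attachment, searching
  both the newborn rows below the head and up to 8 rows of the supporting
  stalk below the base.  The simulated spine is a knob of roughly constant
  width on a narrower stalk; its anatomical neck is at the junction, which
  is where a human reading the silhouette would measure it.  A neck search
  confined to newborn rows would return RCW ≡ 0 for every simulated spine
  and make the mushroom class unreachable.

RAW = (w_head + w_neck)/(2h) and RCW = (w_head − w_neck)/h feed the flow
chart: branching structure → branched; RAW < 0.4 → thin; RCW < 0.25 →
stubby; otherwise mushroom.  Branching is detected as ≥ 2 runs of ≥ 2 px
separated by ≥ 2 px persisting over ≥ 3 consecutive rows — exactly testable
and free of a skeletonisation dependency.  For branched spines the head
width is not reported.

## Dendrite spine counting

Laterals nucleate along the trunk with the Turing spacing but fuse at their
bases within a few hundred time units, after which connected-component
counts measure the topology of the merged web rather than the number of
spines (under 8-connectivity the entire newborn structure is typically one
component).  The density protocol therefore:

1. runs each condition to a *matched growth stage* — the first time its
   protruding newborn area (newborn cells ≥ 3 px outside the trunk band;
   strongly inhibited conditions thicken the trunk into a sheath that never
   protrudes) reaches 400 px and at least one lateral has crossed the
   counting lines, capped at t = 4000;
2. counts spines as runs of newborn cells crossing the two vertical lines
   5 px outside the trunk band (excluding 12 apical and 5 basal rows), and
   reports the maximum of this count over the run — each spine that ever
   distinctly protruded is counted once, merges notwithstanding;
3. averages the count over 8 seeded noise runs: individual runs have a
   count noise of ±2–3 spines, comparable to the spacing differences
   between neighbouring conditions.

The per-image `spine_density` operator (remove trunk band, label 4-connected
components, count area ≥ 4 px) is retained for classifying and counting
protrusions in isolated silhouettes, where no merging occurs.

## Turing analysis

Freezing (S, Y) decouples an A–H subsystem whose positive steady state
solves a cubic in A (after eliminating H = (cA²S + σ_H)/ν); roots are taken
from the cubic companion matrix and polished by bisection, preferring the
root that is stable without diffusion (the analysis presupposes one); the
Y = 0 case has the closed form A* = ν/μ.  The dispersion relation λ(k) is
the larger root of the 2×2 quadratic for J(k) = J − diag(k²D_A, k²D_H)
(complex pairs compared by real part), evaluated on a log-spaced grid
k ∈ [0.01, 10] (wavelengths below ~0.6 are unrepresentable at dx = 0.3)
with bounded scalar refinement of the peak; Λ = 2π/k_m.  Instability is
decided both by the classic inequality D_H f_A + D_A g_H > 2√(D_A D_H det J)
(with tr J < 0, det J > 0) and by the sign of the dispersion maximum; the
two routes are asserted to agree.

For a dendrite run, every cell whose cytoskeleton switches on during stage 2
traces an (S, Y) curve that transits the instability region while Y rises.
The wavelength of a condition is the median of Λ evaluated at the *last*
in-region curve point of each such nucleation site — a deterministic variant
of picking the curve–region intersection by eye, and far more stable than
any single hand-chosen probe point.  The S–Y curves themselves are pure
readouts of the recorded trajectory and do not depend on δ_A/δ_H; only the
instability region moves.

## What the tests do and do not show

The epsilon-scan boundaries (mushroom ≤ 0.02, stubby ≤ 0.04, thin ≤ 0.70,
branched above), the exogenous shape conversions, the density monotonicity
in δ_A and δ_H and the opposing wavelength orderings are all reproduced by
the defaults above.  Known limitations:

* The epsilon density sweep is *not* flat in this implementation: counts
  fall roughly twofold from ε = 0.5 to ε = 2.5.  High-ε conditions grow
  branched-dominant laterals whose arbors suppress neighbours (the same
  space-competition effect that caps the other sweeps), so a fixed-stage
  count conflates shape with density.  Only the final pair (ε = 2.0 vs 2.5)
  is approximately equal.
* Realized counts carry a granularity of ±1 spine even after seed
  averaging; orderings are reproducible under the default protocol but the
  margins at neighbouring conditions can be below one spine.  In
  particular, the δ_H = 0 vs δ_H = 5·10⁻⁵ pair ties exactly under the
  default 8-seed ensemble (10.75 vs 10.75; a 16-seed diagnostic separates
  them at 11.06 vs 9.88), so the strict five-point ordering test for δ_H
  fails at that single pair while the overall collapse (10.75 → 0.25
  across the range) is unambiguous.
* The simulation is 2-D and the silhouettes are pixel masks; nothing here
  emulates optics, staining variability or curved dendrites, so passing
  tests validate the model's internal logic, not agreement with microscopy.
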