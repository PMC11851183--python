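# Methods

`arcadapt` implements an online plan-adaptation workflow for single-arc proton
therapy and everything needed to exercise it end to end on synthetic phantoms:
a phantom/deformation generator, an analytic pencil-beam dose engine, an
arc-plan model with energy-layer sequencing, the geometric adaptation with
energy-pattern preservation, the two-criteria spot selection with
frozen-background weight re-optimization, and DVH-based plan evaluation.

## The adaptation workflow

A proton arc plan delivers one energy layer (or a few) per gantry control
point; a *cluster* is the set of spots sharing a layer and a control point on
the initial plan. Increases of energy between consecutive layers in delivery
order ("switch-ups") are slow on real machines because the bending magnets
must ramp up, so the angular positions of switch-ups are a precious property
of the initial plan. When the anatomy changes between the planning image (CT1)
and the image of the day (CT2), the workflow adapts the plan in two stages:

**Geometric adaptation.**
1. Each spot's Bragg-peak position is computed on CT1 by raytracing its
   central ray to the depth where the cumulative water-equivalent path length
   (WEPL) equals the energy's range, and pushed through the CT1→CT2
   displacement field.
2. The displaced positions are converted back to beam-eye-view coordinates,
   and the energy required to reach each displaced depth is obtained by
   raytracing CT2 and inverting the range–energy law. Because spots of one
   cluster now require different energies, each cluster is forced back to a
   single energy: the median of its members' updated energies (lower middle
   value for even counts), snapped to the nearest machine energy (ties toward
   the lower energy). Scanning clusters in delivery order, an energy increase
   relative to the *previous cluster's enforced energy* is accepted only where
   the initial pattern itself has a switch-up; elsewhere the cluster inherits
   the previous assignment, so runs of illegal increases collapse onto a
   plateau. This guarantees, unconditionally, that the adapted pattern's
   switch-up positions are a subset of the initial ones. Weights are never
   modified and spots are never deleted.
3. The dose of the adapted plan at the CT1 weights is recomputed on CT2; if it
   is not clinically acceptable, the per-spot dose-influence vectors from this
   computation are kept for stage two.

**Spot-weight adaptation.** Two criteria choose the spots to re-optimize:
first the smallest set of spots carrying at least a fraction p (default 0.65)
of the total CT1 weight — spots with small weights would have noisy beamlets
under proportional proton allocation and make poor re-optimization handles;
then, among those, the spots whose objective derivative passes a threshold t
(default 3). The remaining spots are *not deleted*: they keep their CT1
weights and contribute a fixed background dose, precomputed once per scenario,
so the optimized total dose is `TD = w_d,1 · D_d + w_s · D_s`. Only the
selected weights are optimized.

## Dose engine

The engine is a deliberately simple analytic pencil-beam model. What the
workflow requires of it is exact linearity of dose in the weights,
reproducibility, and Bragg peaks at the right depths; clinical dosimetric
accuracy is a non-goal.

* **Range–energy law**: Bragg–Kleeman `R = α E^p` with α = 0.0022 cm·MeV⁻ᵖ and
  p = 1.77 (standard water values), machine interval 70–230 MeV.
* **Raytracing**: equidistant sampling (default step = min(voxel spacing)/2)
  of the RSP along each ray, trilinear interpolation, cumulative WEPL. Rays of
  one control point are traced in a single vectorized call.
* **Depth dose**: a peak-normalized curve with an entrance plateau (0.12 of
  the peak), a Gaussian rise of width 6 mm WEPL to the peak at residual range
  zero, and a Gaussian distal falloff with straggling width
  `σ_R = max(0.3 mm, 0.012 R)`. The plateau value is chosen low enough that
  the on-axis voxel dose still peaks at the Bragg depth although the lateral
  σ grows with depth (σ(z) = 3 mm + 0.03 z). Voxel dose = depth dose × a
  normalized 2-D lateral Gaussian; voxels below 10⁻³ of the beamlet maximum
  are dropped.
* **Units**: beamlets are "Gy per unit weight" up to an arbitrary fluence
  unit. The end-to-end study calibrates the unit per plan so that the uniform
  prescription-scaled initial weight equals 1; weights are then dimensionless
  relative fluences of order one, which is what makes an absolute gradient
  threshold t transferable across phantoms.
* **Monte-Carlo statistics emulation**: with noise on, every retained voxel
  dose is multiplied by `1 + ε`, `ε ~ N(0, c/√protons)` clipped at −1
  (c = 1), seeded per (seed, spot id). Proton allocation is either uniform
  (default 10⁴ per spot, used for reference plans) or proportional to the CT1
  weights with a floor of one proton (default total 3·10⁷, used for adapted
  plans). Noise is off by default so every test is deterministic; the noise
  law itself is verified by a 200-seed Monte-Carlo test.
* **Error scenarios**: a setup error translates the isocenter before
  raytracing; a range error scales the RSP grid. One influence matrix is
  computed per scenario. The default robust set is the nominal plus six
  single-axis ±4 mm shifts plus ±2.6 % range scalings (9 scenarios).

## Phantoms and deformations

The phantom is a head-and-neck-like stand-in: a water elliptical cylinder
(RSP 1, with a smooth seeded ±1.5 % texture) in air (RSP 0.001, never 0, so
WEPL integrals stay defined), a spherical high-dose target, an optional
low-dose target shell, a cord-like serial OAR posterior to the target, and an
optional air cavity. The seed jitters the target centre and the RSP texture,
so seeds produce genuinely distinct anatomies. Deformation fields map CT1
points to CT2 points (push-forward for spot positions; images are resampled
through a fixed-point-inverted field). Taper weights are C¹ cubic smoothsteps
of the Euclidean distance transform, so plateaus are exact: a `rigid_shift`
moves the body interior by exactly the requested vector (fading to zero at
the body surface, zero outside the dilated body), a `target_shift` translates
the dilated target region, `target_shrink` contracts radially toward the
target centroid with exact linear factor (1−f) inside the target, and
`surface_erosion` displaces the body surface inward. Fields whose Jacobian
determinant is non-positive anywhere are rejected.

What the generator does *not* emulate: Hounsfield-to-RSP calibration, bone or
dental artifacts, weight-loss-induced body-contour change combined with
internal sliding, and registration error — the fields are ground truth by
construction. Passing tests therefore demonstrate the workflow's mechanics
and invariants, not its clinical accuracy on real registrations.

## Plan construction

Spots are laid out per control point on a hexagonal beam-eye-view lattice
(anchored at the BEV origin, so a larger margin always yields a superset of
positions) covering the projection of the margin-dilated target; one spot per
(position, layer) whose Bragg depth falls inside the dilated target along the
ray. Energy layers are sequenced by a simple heuristic that stands in for
commercial selection algorithms: the arc is split into at most
`max_switch_ups + 1` contiguous sectors, and within each sector the union of
candidate energies is delivered in strictly descending order, so energy
increases can only occur at sector boundaries and the switch-up budget holds
by construction.

## Optimization

The objective is a weighted sum of one-sided quadratic penalties, each
mean-normalized over its ROI: `max_dose` → mean over ROI voxels of
max(0, d−L)², `min_dose` → mean of max(0, L−d)², `mean_dose` →
max(0, mean(d)−L)². Robust terms take the maximum of the term value over the
scenario set (composite worst case per term; ties resolve to the lowest
scenario index, and the gradient flows through the argmax scenario). The
optimizer is projected gradient descent with an Armijo backtracking line
search (c = 10⁻⁴, shrink 0.5), the step warm-started from the previous
accepted step and allowed to double. The trace of accepted objective values
is non-increasing by construction; iteration stops at `max_iter` (default
500) or when the relative decrease over 10 iterations falls below 10⁻⁶. The
gradient-criterion default mode is `magnitude` (|∂F/∂wᵢ| > t): spots that
need weight *increases* carry negative derivatives, and excluding them would
cripple coverage recovery; the literal signed comparison is available as
`mode="signed"`.

## Evaluation conventions

DVH metrics are voxel-exact: D_q% is the largest dose d such that at least
q % of the ROI's voxels receive ≥ d (so 100 voxels dosed 1..100 Gy give
D98 = 3 Gy); D_vcc is the dose of the ⌈v / voxel-volume-in-cc⌉-th hottest
voxel. Worst-case values are per-metric over the optimization scenario set:
minimum over scenarios for goals of the form "metric > level", maximum for
"metric < level". Default clinical goals are prescription-relative
(D98 > 95 % of prescription per target; for 70 and 54.25 Gy prescriptions
this reproduces 66.5 and 51.54 Gy) plus an absolute 44 Gy max-dose cap on the
serial OAR.

## The end-to-end study

`arcadapt.experiments.run_adaptation_study` reproduces the qualitative
adaptation pattern on one synthetic case. Study conditions (all defaults of
`StudyConfig`): a 64³-voxel phantom at 3 mm spacing with a single high-dose
target (70 Gy) and a serial OAR 38 mm posterior; a 36-control-point arc, 6 mm
hexagonal spot spacing, 6 mm spot-placement margin (at least the setup error
plus the penumbra width, which is what makes worst-case-robust coverage
attainable at all), a 4-switch-up budget; worst-case robust optimization of
every plan over the 9-scenario set (±4 mm setup, ±2.6 % range), 500 maximum
iterations; the anatomical change is an 8 mm target shift toward the OAR.
Objective priorities (coverage 150, homogeneity 60, OAR 80, falloff ring 15,
body 10, with the conformality ring spanning 8–20 mm outside the target —
outside the robustness margin) play the role of the per-case constraint
weighting that clinical planners tune; they are fixed once for the study.
Problem sizes were chosen so the full study runs in minutes on one CPU; the
36-control-point arc is the desk-scale stand-in for the clinical
one-per-degree arc and is a configuration knob, not a semantic change.

The study measures: D98 of the (moved) target for the un-adapted plan, the
geometric-only adaptation, the smart adaptation and a full re-optimization
from scratch on CT2 (same spot set, uniform initialization); the OAR maximum
dose; the fraction of spots re-optimized; and the ratio of final objective
values (smart / reference). The pattern mirrors the clinical evaluation: no
adaptation and geometric-only adaptation under-cover, smart adaptation
restores coverage and OAR sparing while re-optimizing a minority of spots.

One honest caveat the study itself quantifies: the partial re-optimization
matches the reference on the *clinical dose metrics* (both meet the goals;
D98 within ~1.5 % of prescription of each other) but not on the raw objective
value — its converged objective sits roughly 20–25 % above the full
re-optimization's. This is structural, not a convergence artifact: the frozen
background cannot re-distribute weight onto spots that were light on CT1 but
are needed after the shift, and the excess persists even when every spot of
the 65 %-weight selection is freed. Agreement should be expected in DVH
metrics (as the clinical evaluation reports), not in objective value.

## Numerical choices and degenerate inputs

* Raytracing discretization bounds every energy-recovery error at roughly
  half a sampling step of WEPL; identity adaptation recovers original
  energies exactly after machine-grid snapping.
* Spots whose displaced peak falls outside the machine energy interval are
  clamped to the interval edge and flagged, never deleted; a flagged fraction
  above 5 % logs a warning and above 50 % aborts the adaptation.
* Empty beamlets (ray misses the grid, or all voxels below the sparsity
  cutoff) are warnings, not errors.
* `select_by_weight` breaks weight ties by ascending spot id, making the
  minimum-cardinality prefix deterministic.
* Even-sized clusters use the lower median so the value stays on the machine
  grid before snapping.
* All generators are pure functions of (configuration, seed); the noise mode
  is seeded per (seed, spot id) so influence matrices are reproducible
  spot-by-spot.

## Known limitations

The pencil-beam model has no nuclear halo, no heterogeneity-induced lateral
disequilibrium, and a parametric (not Bortfeld) Bragg curve; absolute doses
are in calibrated machine units, not clinically commissioned Gy. The
energy-layer sequencing heuristic is a documented stand-in, not a
reimplementation of a commercial algorithm. Synthetic deformation fields are
smooth ground truth; real deformable registration error is out of scope. The
end-to-end study is one synthetic case per seed, not a patient cohort, so it
reproduces the direction and structure of the clinical findings rather than
their magnitudes.
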