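# Methods

This note documents the models implemented in `tlseg`, the numerical
choices behind them, what the synthetic phantoms do and do not emulate, and
the design decisions taken where more than one reasonable reading existed.

## Problem setting and conventions

The input is a 3D scalar volume on a Hounsfield-Unit-like scale in which
the structure of interest — the contrast-filled lumen of an intracranial
aneurysm and its parent artery — is brighter than its surroundings. The
working unit is the voxel: the intended workflow crops a region of interest
(ROI) around the aneurysm first, and all distances and metrics are reported
in voxel units with unit spacing assumed by the numerics (spacing metadata
is carried through I/O for interoperability, and a physical-unit conversion
is a multiplication by spacing).

Internally every grid is indexed (x, y, z); readers normalise from the
on-disk layout. Level-set fields follow the *negative inside* convention:
the segmented region is {φ < 0}, and all speeds F are *outward* normal
speeds evolved by φ_t + F|∇φ| = 0, so F > 0 grows the region. Published
formulations of the region-based and geodesic flows vary in their inside
sign and in whether the speed is written as the right-hand side of
φ_t = |∇φ|(·); both region terms and curvature terms here are mapped onto
the single outward-speed convention so that, in every evolution, brighter-
than-threshold voxels attract the surface and curvature smooths it. This is
the only mapping under which the three documented limiting behaviours hold
simultaneously: the region term alone reproduces the threshold acceptance
rule, the boundary term alone is the geodesic-active-contour flow, and
curvature flow shrinks convex surfaces.

## Segmentation models

**Region Growing Threshold (RGT).** The maximal connected component, under
6- or 26-connectivity (default 26, configurable), of
{x : T1 ≤ I(x) ≤ T2} containing a seed voxel. Implemented exactly via
connected-component labelling; verified voxel-identical to a brute-force
breadth-first flood fill. In the automatic variant the lower threshold is
taken from a converged TLS run and T2 is the volume maximum, leaving only
the seed manual.

**Chan-Vese (CV).** Two-phase piecewise-constant segmentation with outward
speed

    F = λ₂ (I − μ_out)² − λ₁ (I − μ_in)² − α_cv − β_cv κ,

where μ_in/μ_out are the mean intensities over the current {φ<0}/{φ≥0}
partition, recomputed every step from the hard partition (no smeared
Heaviside), and κ = div(∇φ/|∇φ|). Defaults λ₁ = λ₂ = 0.001, α_cv = 0,
β_cv = 0.3. The stationary partition assigns each voxel to the nearer mean,
so on a two-valued image the converged mask is the true region exactly;
this is tested.

**Threshold-based level set (TLS).** Outward speed

    F = α (I − T) − β div(g ∇φ/|∇φ|),    g = 1/(1 + c|∇I|²),

with defaults α = 10, β = 3, c = 0.5. α weights the region term (units:
speed per HU), β the geodesic boundary term. c controls how sharply the
edge-stopping map g falls on intensity edges; the segmented volume is flat
over c ∈ [0.5, 0.7] (tested), which is the recommended range. |∇I| is
computed after a light Gaussian pre-smoothing (σ = 0.5 voxel, configurable,
0 disables) to suppress noise-induced spurious edges. The initial surface
is an axis-aligned box inset 2 voxels from the ROI faces, so no seed is
needed.

## Automatic threshold estimation

Chebyshev's inequality bounds the mass of any population beyond k standard
deviations from its mean: P(|X−μ| ≥ kσ) ≤ 1/k², one-tailed
P(X−μ ≥ kσ) ≤ 1/(1+k²) (at k = 1, at least half the population lies below
one SD above the mean). Modelling foreground and background as two
populations with a shared confidence multiplier k and requiring the
foreground's lower confidence bound to meet the background's upper bound,

    μ_b + kσ_b = μ_a − kσ_a   ⇒   k = (μ_a − μ_b)/(σ_a + σ_b),
    T = μ_a − kσ_a (= μ_b + kσ_b).

An alternative form of the k estimator with (σ_a − σ_b) in the denominator
is retained behind `k_mode="as-printed"` for comparison; it is singular
when the two spreads coincide and can place T outside (μ_b, μ_a), in which
case T is clamped 5% of the band inside the violated end with a warning.
The default (σ_a + σ_b) form is the one consistent with the balance
relation above, is always regular, and keeps T strictly between the means
whenever both SDs are positive.

The outer loop: statistics from the current mask → k → T_i → a block of 25
TLS PDE steps at fixed T_i → new mask, stopping when |T_i − T_{i−1}| <
0.5 HU or after 30 iterations (the loop is deterministic; the history of
every iteration is recorded and exportable as CSV). The initial mask is a
Chan-Vese pre-segmentation started from the box surface. Two refinements
matter in practice:

* **Partial-volume exclusion.** Boundary voxels average the two tissues
  (CT partial-volume effect) and belong to neither population; including
  them inflates σ_a and biases T toward the background, which on thin
  vessels costs a one-voxel over-segmentation ring. Both statistics
  regions are therefore eroded by one voxel (`stats_erosion`, fallback to
  the raw regions if an eroded one has fewer than two voxels) so the
  estimator sees the homogeneous cores. The background region is the ROI
  complement of the mask.
* **Two-valued degeneracy.** On an exactly two-valued volume both SDs are
  zero and the balance relation degenerates; the limiting balanced value
  T = (μ_a + μ_b)/2 is used for that iteration.

## Numerical scheme

* Explicit Euler in time, dt = 0.5/max|F| each step (CFL in voxel units).
* The speed is split into a hyperbolic part (region/balloon terms), which
  multiplies a Godunov-upwinded |∇φ| with the branch chosen per voxel by
  the sign of F, and a parabolic part (curvature and geodesic terms), which
  multiplies the central-difference |∇φ|. Upwinding the parabolic part
  would add O(h) numerical viscosity — enough to break the shrinking-sphere
  law below — so it is kept central.
* Curvature κ = div(∇φ/|∇φ|) by central differences with an ε = 1e-8
  regularised divisor, clipped to |κ| ≤ 6 (the curvature of a one-voxel
  sphere is 4; larger values are sub-grid artefacts that would throttle the
  CFL step).
* One-sided differences at the grid faces; no wraparound.
* Reinitialisation every 20 steps: φ is rebuilt as the exact signed
  Euclidean distance to the boundary of {φ < 0} (distance-transform based,
  half-voxel offset so boundary voxels carry ±0.5), except on voxels with a
  6-neighbour of opposite sign, where the first-order local estimate
  φ/|∇φ| is kept — this preserves the sub-voxel position of the zero
  crossing that a plain mask distance transform would snap to the voxel
  midplane.
* In the Chan-Vese evolution the region speed is additionally saturated at
  its 90th absolute percentile (`clip_quantile`, 1.0 disables). From a box
  initialisation on a background-dominated ROI the two means start nearly
  equal and the separating forces are orders of magnitude below the few
  brightest-voxel speeds that set dt; saturation is sign-preserving (the
  stationary partition is unchanged — verified against an unclipped run)
  and cuts convergence from ~1400 to ~260 steps.
* Evolutions run full-grid (no narrow band); ROI cropping is the intended
  cost control. Stopping: interface change below 0.1% of the voxels
  between reinitialisation cycles, or the step budget (CV default 2000;
  TLS inner blocks are fixed at 25 steps between threshold updates).
* Verified laws: a radius-10 sphere under F = −βκ follows
  R(t)² = R₀² − 4βt within 5% down to R = 5; constant F = 1 advances the
  interface at 1.0 ± 0.1 voxel per unit time.

## Validation metrics

For ground-truth voxel set S1 (volume V1) and test set S2 (V2):
VD = |V2−V1|/V1·100; overlap JM as Jaccard |S1∩S2|/|S1∪S2|·100 by default
with a Dice mode 2|S1∩S2|/(|S1|+|S2|)·100 always reported alongside (both
conventions are in circulation, and identical masks must score 100 either
way); rfp = (|S2|−|S1∩S2|)/|S1|·100 and rfn = (|S1|−|S1∩S2|)/|S1|·100,
both normalised by the ground-truth volume. Surfaces are foreground voxels
with a 6-connected background neighbour (grid faces count as background);
HD is the symmetric Hausdorff distance and MASD the mean of the two
directed mean nearest-surface distances, between voxel centres, in voxels.
Nearest-neighbour queries use a KD-tree and are verified to 1e-9 against an
O(n²) all-pairs oracle.

## Phantoms: what they emulate, and what they do not

Each phantom is an analytic solid — a tubular parent artery (straight, or
bent with a circular-arc sagitta profile), a saccular aneurysm sphere, and
optionally a small bleb protruding from the sac — voxelised by the
centre-inside rule, so ground truth is exact by construction. The volume is
I_bg + (I_fg − I_bg)·blur(indicator) + N(0, σ): Gaussian blur of the
continuous indicator before noise emulates CT partial-volume averaging at
boundaries; white Gaussian noise emulates detector noise. Defaults
I_fg = 200, I_bg = 100, σ = 10, blur 0.8 voxel: a contrast-CTA-like
separation that is not trivially separable after blurring. Generation is
deterministic per seed, and the segmenters themselves are seed-free.

The fixed four-case battery (all 64³): straight artery + medium sac;
curved artery hugging a large sac; sac with a bleb; small sac at reduced
contrast (I_fg = 160). These probe the failure modes that matter —
curved-vessel coverage, bleb capture, low contrast — at desk scale.

The phantoms do **not** emulate beam hardening, streak artefacts,
inhomogeneous contrast filling, vessel-adjacent bone, or vascular trees
beyond one parent artery. Passing the battery therefore demonstrates the
correctness and internal consistency of the algorithms under the intensity
model they assume, not clinical-grade performance; on clinical data the
ROI choice and the homogeneity of contrast filling will dominate.

## Degenerate inputs and failure behaviour

Empty or single-phase masks, inverted contrast (μ_a ≤ μ_b), out-of-range
seeds, and singular k denominators raise typed errors rather than produce
silent nonsense; a level-set evolution that collapses to an empty or full
grid reports the stage and iteration at which it died. The battery runner
records per-case failures and continues.

## Known limitations

* Finite differences assume isotropic unit spacing; anisotropic data
  should be resampled upstream (resampling is out of scope).
* Full-grid evolution costs O(grid) per step — intended for cropped ROIs,
  not whole scans.
* The threshold model is global: one T for the ROI. Slowly varying
  contrast within the ROI is not modelled.
* Overlap/volume metrics are voxel-count based; no meshed-surface or
  sub-voxel metric variant is provided.
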