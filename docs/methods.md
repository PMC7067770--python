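# Methods

`myotomo` quantifies denervation damage in muscle from reconstructed 3D
tomography stacks. The biological signal is the **muscle fibre space** — the
interstitial region inside the muscle bundle left behind when fibres atrophy
(fascia shedding, edema, inflammatory infiltrate). Its volume and area
fraction grow with the severity of nerve injury, so segmenting it and summing
voxels per slice yields an objective injury metric for a single specimen.

Because the raw animal images behind this kind of study are generally not
shared, the package ships a ground-truthed synthetic phantom generator, and
every downstream stage is validated against phantoms whose answer is known
voxel by voxel.

## Phantom model

A cross-section of healthy muscle is a packing of polygonal fibres. We
emulate it as a Voronoi tessellation of a circular bundle:

- `n_fibers` seed points are placed quasi-uniformly (Mitchell best-candidate
  sampling) in a disc of radius `bundle_radius_frac × image half-width`;
  each fibre is the Voronoi cell of one seed, extruded along z with a
  small sinusoidal centroid jitter (`jitter_px`, default 1 px) so fibres are
  gently undulating tubes rather than prisms.
- **Atrophy** `a ∈ [0,1]` shrinks each cell toward its centroid by the factor
  `1 − 0.02 − 0.45·a`; the 2 % baseline gap renders the interstitial line
  visible in healthy tissue, and the widening gap at larger `a` is the
  fibre-space signal. Directions in which a cell is bounded by the bundle
  circle rather than a neighbour are *not* shrunk ("fascia anchoring"): the
  outer envelope of the bundle stays put while interior space widens. This
  matches what the downstream contour measurement (closing + hole filling of
  the fibre mask) can observe — space outside the fibre envelope is
  unmeasurable by construction — and models interstitial rather than
  sub-fascial widening.
- **Rounding** `r ∈ [0,1]` blends each cell's polygonal radius function
  toward its inscribed circle, reproducing the polygonal-to-round shape change
  of atrophying fibres. Whole-study generation couples `r = a` by default.
- Intensity: fibres at `fiber_intensity` (default 200), interstitial space
  and exterior at `background_intensity` (default 50) — the fibre space
  deliberately sits at the background grey level — plus additive Gaussian
  noise (`noise_sigma`, default 10). Grey levels and SNR are package
  choices (no reference statistics exist for such reconstructions) and are
  config-exposed.
- Default grid 64×128×128 voxels at 1.625 µm/voxel. This is a desk-scale
  stand-in for ~300-slice reconstructions at the same voxel size; full-size
  volumes are a config change.

Truth masks satisfy `space = contour AND NOT fiber` exactly, with
`contour` the bundle disc.

**Injury trajectories.** Two models with days (1, 7, 14, 21):
nerve-section atrophy 0.2/0.4/0.6/0.8 (monotone, non-recovering) and
nerve-crush 0.2/0.5/0.7/0.4 (worst at day 14, partial recovery by day 21).
The uninjured contralateral side receives 60 % of the paired injured-side
atrophy — weaker but non-zero, so the contralateral effect is present.
Synthetic wet weights are `w0·(1 + 0.004·(day−1))·(1 − 0.35·a) + ε`,
`w0 = 0.010 g` (a healthy mouse soleus), `ε ~ N(0, 0.0003 g)`: mild growth,
atrophy removes up to 35 % of mass.

**What the phantoms do not emulate:** phase-contrast edge fringes, ring and
reconstruction artefacts, intensity inhomogeneity, partial-volume blur,
nuclei/inflammatory cells as distinct classes, and anatomically realistic
bundle outlines. Passing the recovery tests therefore shows the pipeline is
correct under its stated contrast model (bright fibres, space at background
level, additive noise), not that it is robust to every artefact of real
beamline data; on real data the denoising and tolerance parameters would need
tuning against manual reference segmentations.

## Denoising

Median filter (cubic window, radius 1 by default) followed by non-local
means, both with reflective edges. The NLM is the classic pixelwise
estimator with uniform patches (patch 5, search 11, applied slice-wise by
default, 3D optional), weights `exp(−max(d² − 2σ̂², 0)/h²)` with σ̂ the
wavelet-based noise estimate and `h = 0.8·σ̂` unless set explicitly. The
shifted-image implementation makes two limits exactly testable: a constant
image is a fixed point, and `h → ∞` recovers the plain search-window mean.
No filter size is hard-coded; all are config parameters.

## Segmentation

Six deterministic steps, each logged with its parameters in a provenance
record:

1. **Region growing** from a seed in the background/fibre-space class: the
   connected component (26-connectivity) of voxels within `tolerance` of the
   seed's initial 3×3×3 neighbourhood mean. The fixed criterion (not a
   running mean) makes the result order-independent. `tolerance="auto"` uses
   the distance from the seed mean to the volume's Otsu threshold. When no
   seed is given one is auto-proposed at the darkest percentile and logged.
2. **Inversion** → fibre mask.
3. **Island removal**, minimum component 27 voxels (3³) — speckle at the
   default voxel size.
4. **Closing + hole filling** → solid bundle contour. Closing uses a
   Euclidean ball (default radius 9 voxels, chosen to bridge the widest
   interstitial gaps the atrophy model produces) computed by two distance
   transforms — exact Minkowski morphology, verified against brute force.
   The contour closing runs in a zero-padded domain so bundles near the
   volume border close against an unbounded background.
5. **Subtraction** `contour AND NOT fiber` → candidate space.
6. **Dark top-hat refinement**: slice-wise grey closing with a disc (radius
   7) minus the image, thresholded by Otsu over the contour, intersected
   with the candidate — discarding candidate voxels that are not actually
   darker than their surroundings. Voxels outside the contour are clamped to
   the bright level first; otherwise the dark exterior makes the open channel
   mouths at the bundle boundary score zero response and exact noise-free
   recovery becomes impossible. Voxels rejected here are reassigned to the
   fibre mask so that `space = contour AND NOT fiber` holds for the final
   result as well.

Foreground operations use 26-connectivity, background/hole filling
6-connectivity (the standard complementary pairing). File-based add/remove
override masks stand in for interactive brush edits and error out when they
overlap. A contour below 1 % of the volume raises a segmentation failure.

None of the numeric parameters above is dictated by the imaging protocol;
they are engineering defaults, live in one config schema, and are echoed in
provenance.

## Quantification and statistics

- Per-slice voxel counts of the space mask along z; the total (voxels and
  µm³ via voxel size cubed) is the injury volume, and the **population**
  standard deviation of per-slice counts summarises how unevenly injury is
  distributed along the muscle. An explicit slice range restricts analysis
  to, e.g., the muscle belly.
- 2D area fractions against the bundle-contour region (not the image frame):
  `fiber_pct = 100·|fiber|/|region|`, `space_pct = 100 − fiber_pct` —
  complementary by construction.
- Baseline deltas `metric(day 1) − metric(day)` per (group, side): worsening
  injury drives space-volume deltas negative; the nerve-crush series returns
  part-way toward zero after day 14.
- Contralateral differences: `non-injury − injury` for weights (positive
  under atrophy), `injury − non-injury` for space metrics (positive when the
  operated side is worse). Both conventions are encoded once in
  `myotomo.quantify`.
- Group comparisons use the two-sided independent-sample t-test, pooled
  variance by default (df = n1+n2−2) with Welch available; tiers
  `‡ p<0.01, † p<0.05, * p<0.1` use strict inequalities. Two identical
  constant samples return t = 0, p = 1; zero variance in both samples with
  different means is an error. No multiple-testing correction is applied.
  A Monte-Carlo harness checks the empirical type-I error at n = 6 per group.

## Numerical and reproducibility choices

- Arrays are `(z, y, x)`, 0-based, z the stack axis. Volumes are float32
  internally; masks boolean, written as 0/255 8-bit TIFF.
- All randomness flows from one master seed; per-volume sub-seeds are CRC32
  hashes of (group, side, day, replicate) mixed with the master seed, kept
  below 2³¹. Reruns with the same config and seed are bit-identical
  (no timestamps in any artefact).
- Otsu thresholds come from scikit-image; degenerate (constant) top-hat
  responses yield an empty refinement instead of a threshold.
- Problem sizes in the shipped tests and acceptance script (96²–128²
  cross-sections, 16–64 slices, 2–3 replicates) are chosen so the whole
  validation suite runs in minutes on one CPU while exercising every code
  path at realistic fibre-to-voxel scale.

## Known limitations

- The space fraction estimate is measured against the *recovered* fibre
  envelope; with strongly rounded, shrunken fibres the envelope itself
  recedes, so absolute volumes are conservative at extreme atrophy even
  though side-to-side and day-to-day contrasts remain correctly ordered.
- Slice-wise (2D) NLM and top-hat are defaults chosen for speed and
  isotropy of the slice plane; fully 3D variants exist (NLM) or would need a
  ball footprint (top-hat).
- No ring-artefact removal, flat-field correction, fibre-instance
  segmentation, or fascia class; these are out of scope.
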