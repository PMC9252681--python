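# Methods

This note documents the models, parameter choices and numerical decisions
behind `hybridseg`, and what the synthetic-phantom results do and do not
show about real data.

## Pipeline model and assumptions

The pipeline assumes 2–3 co-registered, same-grid scalar volumes whose
target lesion is *brighter than its surround on the fused image*. All
stages are deterministic given the configuration, and the stage order is
fixed: median filter → gray stretch → linear fusion → FFCM clustering →
automatic threshold → hybrid level set. Inputs are taken as already
registered; no resampling, reorientation or bias-field correction is
performed.

### Preprocessing and fusion

* `median_radius` (voxels, default 1, i.e. a 3³ window): removes impulse
  noise at the cost of eroding roughly one boundary layer from structures
  whose local surface curvature is high. On small lesions this erosion is
  the dominant accuracy limit of the whole pipeline (see Limitations).
* `stretch.low_percentile` / `high_percentile` (fractions, default 0 / 1 =
  pure min–max): robustness clamp against hot voxels; values outside the
  window clip. A degenerate window (constant channel) maps to all-zero
  rather than erroring so blank channels keep the pipeline alive.
* `stretch.levels` (default 256): output gray range [0, 255]; the fused
  volume is rounded to integers before histogram compression.
* `fusion_weights` (default equal): "linear fusion" fixes only linearity;
  equal weighting is the unique symmetric choice and is applied after
  stretching so modalities contribute on a common scale.

### FFCM

* Updates are the closed-form stationary conditions of the Lagrangian of
  the fuzzy objective: membership ∝ distance^(−2/(r−1)), centers the
  membership^r-weighted mean. A gray level coinciding with one or more
  centers takes membership 1 split over exactly those centers.
* Histogram weighting is an exact reformulation, not an approximation:
  voxels with equal gray values have equal memberships, so the voxelwise
  and histogram-weighted iterations produce identical center trajectories.
  The test suite keeps a brute-force voxelwise FCM as the oracle for this.
* `c` (default 4): background/air, two tissue classes, lesion. Not
  auto-selected; exposed in config. `r` (default 2): the universal FCM
  fuzzifier default; must exceed 1.
* Initialization: centers at evenly spaced quantiles of the *distinct
  level support* (not count-weighted). A count-weighted spread collapses
  several initial centers onto a dominant background mode; coincident
  centers receive identical updates forever and can never separate.
  Distinct level indices are deterministic and collision-free. A seeded
  jitter is available but defaults to off, so runs are reproducible even
  across seeds.
* Convergence: max center shift < `tol` (default 1e-5); hitting
  `max_iter` flags `converged=False` but is not an error.

### Automatic threshold

Otsu's between-class variance criterion on the compressed histogram, ties
resolved to the lowest maximizing level, foreground strictly `> t`. The
default composition (`otsu_top2`) computes the histogram over the union of
the two brightest FFCM clusters: that population is bimodal — lesion mode
plus its bright surround — which is the regime the criterion is designed
for, and the resulting t is a meaningful "gray lower limit of the target".
Restricting to the brightest cluster alone (`otsu_within`, available as a
strategy) degenerates when that cluster is already pure target: the
criterion then splits the target itself, and at zero noise the within-mask
histogram has a single level. In that degenerate case the implementation
falls back to the midpoint of the two brightest cluster centers, i.e. the
clustering's own decision boundary. `otsu_global` (full histogram) mostly
separates brain from background and is kept for completeness.

### Hybrid level set

* Sign convention: φ > 0 inside. The region force α(U−μ) therefore grows
  bright regions. The reported `curvature` field is the mean curvature
  w.r.t. the outward normal (positive for convex interiors; a ball of
  radius R reads +2/R); the evolution itself uses div(k∇φ) directly.
* The update φ ← φ + dt·[α(U−μ) + β(∇k·∇φ + kΔφ)] is explicit Euler on
  the full grid with central differences and edge-replicated borders. No
  upwinding: the advection velocity ∇k is smooth and dt conservative.
  No narrow band: target volumes are ≤ ~128³ where full-grid updates are
  cheap and much easier to verify.
* `dt` defaults to 0.25/(1+6β), a CFL-style bound for the diffusion part
  on unit spacing. Non-finite values mid-evolution raise immediately and
  indicate dt too large.
* `alpha` = `beta` = 1.0 by default; neither is canonical, both exposed.
* `edge_slope` (c in k = exp(−c|∇U|²)) defaults to 400. On
  [0, 1]-normalized multimodal fusions, adjacent-tissue contrast is
  typically ΔU ≈ 0.1, giving central-difference gradients ≈ 0.05; slope
  400 maps those to k ≈ 0.4 while leaving flat regions at k ≈ 1. Slopes
  sized for unit-contrast edges (order 10) leave k ≈ 1 everywhere on such
  data, the edge terms never engage, and unchecked curvature flow erodes
  the target.
* `mu` is by default taken from the automatic threshold, rescaled to
  [0, 1] (`auto_mu`); it is exactly the "gray lower limit of the target"
  that the threshold estimates.
* Redistancing every 20 iterations replaces φ by the signed Euclidean
  distance of {φ > 0}. The raw voxel EDT has diagonal staircase plateaus
  (|∇φ| dips to ≈ 0.56 on oblique interfaces); a σ = 0.9 Gaussian
  regularization is blended in within 3 voxels of the interface (fading
  out by 5), reverting any smoothing-induced sign flip, which restores
  |∇φ| ∈ [0.83, 1.0] near the front while leaving far-field distances and
  the medial axis untouched. Redistancing preserves the sign pattern
  voxel-by-voxel and is exactly idempotent.
* Convergence: relative front-volume change below `convergence_tol`
  (5e-4) for `convergence_window` (10) consecutive iterations, else
  `max_iter` (300) with a non-convergence flag.
* The smoothed Heaviside W_ε(z) = ½(1 + (2/π) arctan(z/ε)), ε = 1.5
  voxels, is used only to report the energy; the PDE path needs no
  Heaviside. Energy descent is meaningful between plain evolution steps;
  redistancing reparametrizes φ away from the zero set and shifts the
  smoothed energy discontinuously without moving the interface.

## The phantom: what it emulates, what it does not

The generator renders air background, a gray-matter-like brain ellipsoid
(semi-axes 0.42·grid), a white-matter-like core (0.26·grid) and
ellipsoidal lesions, each class constant per modality, plus additive noise
(Gaussian default; Rician available since MR magnitude noise is Rician).
Lesion profiles encode the qualitative contrast orderings of melanocytic
lesions — melanotic: T1-bright/T2-dark (FLAIR bright); amelanotic:
reversed; mixed: one lesion with a sub-region of each kind — with default
class means (T1, T2, FLAIR) of background (5,5,5), gray (110,140,130),
white (150,100,110), melanotic lesion (240,40,240), amelanotic lesion
(60,230,210) on a [0, 255] scale chosen to match the stretch output. The
absolute values are free parameters (the qualitative literature gives
orderings, not intensities); they are the package's documented choice and
give a fused lesion–tissue contrast of ≈ 0.1, a regime the default
level-set parameters are sized for.

The reference experiment uses a 64³ grid, one melanotic lesion of
semi-axes (10, 8, 7) voxels, σ = 5 Gaussian noise. Rasterization tags a
voxel as lesion when its center lies inside the ellipsoid; for semi-axes
≥ 5 at generic centers this matches the analytic volume to ≈ 2% (an
integer-radius sphere centered exactly on a half-voxel lattice point is a
degenerate resonant case and not representative).

What passing phantom tests do **not** show: robustness to partial-volume
boundaries, bias fields, texture inside lesions, registration error,
anatomy-shaped tissue, or lesions that are not brighter than their
surround on the fused image. The phantom validates the algorithmic
contracts, not clinical performance.

Problem sizes in the test and acceptance runs (16³ oracle comparisons,
48³ analytic/curvature audits, 64³ end-to-end phantoms) are the package's
desk-scale reference conditions; all complete in seconds.

## Known limitations

* Median filtering erodes ~one boundary layer; on the 64³ reference
  lesion this caps end-to-end Dice near 0.99 even at zero noise, and the
  relative cost grows as lesions shrink.
* Eq.-style evolution without the |∇φ| transport factor is valid only
  near signed-distance form; the redistancing cadence (20 iterations) is
  a compromise, not adaptive.
* Otsu-based μ assumes a bimodal target/surround population; extremely
  unbalanced populations can bias t toward the dominant mode.
* Explicit Euler limits dt; stiff parameter choices (large β) evolve
  slowly rather than unstably.
* Single-lesion logic end-to-end: nothing prevents multiple disjoint
  recovered components (an optional largest-component filter exists, off
  by default), but metrics treat the union.
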