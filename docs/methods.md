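# Methods

## Problem and model

Given a 2-D 8-bit B-mode echocardiogram frame, the task is to delineate the
endocardial boundary of a chamber cavity: a connected dark region (blood
pool) surrounded by brighter myocardium inside the fan-shaped imaging
sector. The method combines an intensity model (maximum-entropy
thresholding of the gray-level histogram) with a geometric model (level-set
curve evolution under constant + curvature speed). Both halves are
classical; the package's value is a tested, reproducible composition with
a ground-truthed synthetic data source.

## Maximum-entropy threshold

The 256-bin histogram g(i) is split at a candidate t into class 1 = [0, t]
and class 2 = [t+1, 255]. Within each class the masses are renormalized,
kᵢ = g(i)/Σ_class g(j), and the class entropy is H = −Σ kᵢ ln kᵢ (natural
log, 0·ln 0 := 0; H equals ln m exactly when the class's m nonzero bins
are equal). The threshold maximizes D(t) = H₁(t) + H₂(t).

Conventions, fixed for reproducibility:

* splits leaving a class empty are **excluded** from the search rather than
  scored zero (otherwise the degenerate all-one-class split can win);
* ties break to the smallest t;
* the search runs on the raw integer histogram. Exponential smoothing
  Y(a) = (1−β)·Y(a−1) + β·H(a), seeded with Y(−1) = g(0), exists for peak
  finding only, where raw counts fluctuate bin to bin.

The production search uses cumulative sums (O(256)); the test suite checks
it bin-for-bin against a naive exhaustive reimplementation.

A property worth knowing: on histograms dominated by a tall bright mode
with a thin "ramp" of partial-volume bins between the modes, the entropy
objective keeps rising as ramp bins join the dark class, so t* lands close
to the bright mode — the threshold mask then overshoots the cavity by a
thin halo along the blurred edge. The pipeline's level-set stage is
calibrated around this behaviour (below).

## Gaussian template smoothing

Speckle suppression uses the isotropic 2-D Gaussian template
H(a,b) ∝ exp(−(a²+b²)/(2λ²)) sampled on a (2r+1)² window, r = ⌈3λ⌉ by
default (>99.7 % of the mass). Kernels are normalized to unit sum so the
operation is a convex combination: constants are preserved, the intensity
range never widens, and the image mean moves at most by rounding (½).
Borders are mirror-reflected without repeating the edge pixel; outputs are
rounded half-up and clipped to [0, 255].

## Level-set evolution

The contour is the zero level set of φ, negative inside. With outward
normal n = ∇φ/|∇φ| and curvature κ = div(n) (positive for a convex
interior), the front moves with outward speed F = β − w·κ, i.e.
φₜ = −β·|∇φ| + w·κ·|∇φ|. Positive β expands; the curvature term alone
shrinks a circle at dr/dt = −w/r, giving the analytic benchmark
r(t) = √(r₀² − 2wt) used in the tests.

Numerics:

* Godunov upwinding for the constant term, central differences for κ,
  explicit Euler at dt = 0.45/(|β| + 4w) (unit grid);
* |∇φ| floored at 1e-8 in the curvature quotient and κ clipped to ±1
  (the grid-resolution bound) so the medial axis, where ∇φ degenerates,
  cannot destabilize the step;
* updates restricted to the narrow band |φ| ≤ 6 px; the outside is frozen
  bit-exactly;
* reinitialization rebuilds φ as the **exact** Euclidean distance to the
  subpixel zero contour (marching squares → point-to-polyline distance),
  keeping the sign of the old field, so the front moves < 0.5 px and
  |∇φ| returns to ≈1. It runs every 20 iterations, or sooner whenever the
  accumulated front displacement since the last rebuild reaches 45 % of
  the band half-width — without that trigger a fast constant-speed front
  outruns the frozen band between rebuilds and stalls;
* initialization from a binary mask uses signed Euclidean distance
  transforms with a half-pixel offset placing the zero crossing on the
  pixel-boundary interface;
* stopping: mean |Δφ| over the band < tol (default 1e-3) or max_iters;
  a vanished zero set raises a collapse signal carrying the last valid
  field.

Measured on a 128² grid: curvature flow tracks the analytic circle to
1.2 % at t = 200; constant flow tracks linear growth to 0.6 % over
50 steps (both recomputed by `scripts/acceptance.py`).

## Segmentation pipeline

Stages: Gaussian smooth (λ = 0.5 px) → histogram over the ROI →
maximum-entropy threshold → dark-class mask (≤ t*, polarity switchable)
→ largest 8-connected component (ties by topmost-leftmost bounding box),
holes filled, min_area = 25 px → signed-distance init → level-set
refinement → final mask {φ < 0} and its zero contour → chamber metrics
(area, mean gray to 2 decimals, equivalent diameter 2√(area/π)).

When an ROI (e.g. the imaging sector) is given, it is eroded by 2 px
before both histogramming and masking, so partial-volume pixels on the
sector border are not mistaken for chamber; without an ROI the full frame
is used — on sector images the dark surround then dominates, so supplying
the sector mask is strongly recommended (the CLI accepts `--roi`).

**Speed calibration.** Because the entropy threshold sits near the top of
the blurred cavity edge ramp (see above), the threshold mask carries a
halo of roughly 0.5–1.6 px outside the true boundary, thicker the less
in-class spread the histogram has. The defaults therefore use a small
*inward* constant speed, β = −0.12, with w = 0.5 and 45 iterations
(≈1.2 px total retraction at the CFL step), which centres the boundary
across the noise range studied; λ is kept at 0.5 px because stronger
pre-smoothing widens the edge ramp and hence the halo. On the seeded
phantom suite this yields mean Dice 0.96–0.97 (0.99 on the noiseless
phantom), with accuracy degrading monotonically as speckle grows through
{0, 0.2, 0.5}. These constants are calibrated to phantom geometry at the
default 128 px scale; for other scales or modalities they are config
fields, not constants.

## Synthetic phantoms

Each phantom is: background 5, imaging sector (apex top-center, default
opening 75°, depth 98 % of the frame) at myocardium_mean = 180, cavity
ellipse (default semi-axes 22 × 16 px at (70, 64) on a 128 px grid) at
cavity_mean = 30; each pixel multiplied by unit-mean gamma speckle with
relative standard deviation speckle_scale = 0.2 (shape 1/s², scale s² —
the standard fully-developed-speckle surrogate); blurred by the Gaussian
template with blur_sd = 0.5 px; clipped to [0, 255]. The truth mask is
the exact ellipse interior. blur_sd is kept at half a pixel so bright-wall
bleed across the ≈120 px cavity perimeter shifts the cavity's sample mean
by well under 5 gray levels, preserving the generator's contract that the
cavity region's mean matches cavity_mean; the wall_thickness field (6 px)
is a fit margin ensuring a bright rim between cavity and sector edge.
Suites jitter the semi-axes by ±20 % and the rotation uniformly over
[0°, 180°), with all randomness flowing from one seed (per-sample subseeds
derived by counter).

What the phantoms do **not** emulate: depth-dependent attenuation and
focusing, anisotropic speckle correlation, wall texture, valve/papillary
structures, shadowing, and motion. Passing the recovery tests shows the
pipeline is correct and well-conditioned under the stated intensity model;
it does not certify clinical accuracy.

## Problem sizes and determinism

Validation uses 128² grids, a 10-phantom suite, curvature flow to t = 200
(1778 steps) and 50 random histograms for the threshold cross-check —
sizes at which the analytic comparisons are already tight. Every stochastic
component takes an explicit integer seed; identical seeds give
byte-identical phantoms and identical segmentations.

## Known limitations

* The entropy threshold is global; strong intensity inhomogeneity would
  require local thresholding, out of scope here.
* The level-set speed has no image-coupled term, by design: the refinement
  is purely geometric, so the speed calibration carries the image
  information. A geodesic/region term would remove that coupling but is a
  different method.
* First-order upwinding is diffusive; high-curvature detail below ~2 px is
  smoothed away.
* Multi-chamber labeling, cine sequences, and clinical indices (EF, LVEDD)
  are not computed.
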