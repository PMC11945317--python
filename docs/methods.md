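# Methods

`splatplant` implements the post-capture computational stages of a
turntable plant-phenotyping pipeline built on 3D Gaussian splatting
(3DGS): converting a trained splat scene into a dense metric point
cloud, removing the baked-in background, cleaning the cloud, scoring it
against a scanned ground truth, scoring renders against held-out
photographs, and planning the turntable camera poses in the first
place. This note records the models, the parameters that matter, and
the design choices made where the procedure was genuinely open.

## The scene model

A splat scene is a set of `n` anisotropic 3D Gaussians. Gaussian `i`
has centre `mu_i` (metres), 1-SD axis lengths `s_i` (metres), a unit
quaternion `q_i` giving the rotation `R_i`, an opacity
`alpha0_i in [0, 1]`, and 16 real spherical-harmonic (SH) coefficients
per colour channel (degree 3). The covariance is
`Sigma_i = R_i diag(s_i^2) R_i^T`; the "volume" of a Gaussian is its
1-SD ellipsoid volume `(4/3) pi s1 s2 s3`. On disk we use the de-facto
binary-PLY splat dialect (62 float32 properties per vertex; scales
stored as natural logs, opacity as a logit, quaternions in (w, x, y, z)
order, normals written as zeros). Two `f_rest` layouts exist in the
wild, so the SH ordering is a reader/writer switch
(`channel-major`, the default, or `coefficient-major`).

## Point-cloud extraction

Selecting only Gaussian centres gives a cloud far too sparse for
surface comparison, so the extractor fixes a total budget (default
10,000,000 points) and distributes it across Gaussians in proportion to
size, so larger Gaussians generate more points. Fractional quotas are
rounded with the largest-remainder (Hamilton) method, ties to the
lowest index: the budget is conserved *exactly*, the allocation is
deterministic, order-equivariant, and monotone in volume. "Size" is
the 1-SD ellipsoid volume; an opacity-weighted mode
(`size_mode="volume_x_opacity"`) is available behind a flag because
either reading of "relative size" is defensible.

Before allocation the scene is pre-filtered: Gaussians with centres
outside a metric crop box (default 1 x 1 x 1.5 m at the origin — the
turntable frame's plant region), with opacity below 1 % (strict `<`),
or in the top 2.5 % of the remaining population by volume (these are in
practice background structure) are discarded. Cropping is applied to
Gaussian *centres before sampling* rather than to sampled points after;
at these thresholds the difference is limited to partial tails of
box-straddling Gaussians and avoids orphaned fragments.

Each Gaussian is sampled i.i.d. from `MVN(mu, Sigma)` conditioned on
Mahalanobis distance <= 2.5 SD: draws beyond the bound are rejected and
regenerated, which bounds every point inside the ellipsoidal core. For
a 3D Gaussian the squared Mahalanobis radius is chi-square with 3
degrees of freedom, so the unconditional acceptance rate is
`P(chi2_3 <= 6.25) ~= 0.900` and the truncation shrinks the sample
covariance to `c * Sigma` with
`c = E[r^2 1{r^2<=6.25}] / (3 P(chi2_3<=6.25)) ~= 0.828`; both facts
are used as independent oracles in the tests. Regeneration is bounded
(default 100 rounds); any stragglers are projected radially onto the
2.5-SD shell and counted in the log — in practice the fallback never
triggers at the ~0.9 acceptance rate. Sampling uses a per-Gaussian
`numpy` generator keyed by `(seed, original index)`, so clouds are
bit-reproducible and invariant to scene ordering.

## Colour assignment via contribution tracking

A Gaussian's own SH colour can be meaningless when it is nearly
transparent or always occluded. Colours are therefore taken from the
*rendered* images: a CPU splat renderer projects each Gaussian to the
image plane through the local affine pinhole Jacobian (EWA-style
2D covariance `J W Sigma W^T J^T + 0.3 I` px^2), depth-sorts by mean
camera depth, and composites front to back with
`w_i = alpha_i prod_{j<i} (1 - alpha_j)`,
`alpha_i = alpha0_i exp(-d^T Sigma2D^{-1} d / 2)` clipped at 0.99 so
transmittance stays positive. Support is the 3-SD 2D Mahalanobis
ellipse (alpha treated as zero outside), evaluated over the ellipse's
bounding box. The renderer records, per Gaussian, the pixel across all
cameras where `w_i` peaked (ties: lowest camera, then row-major pixel);
every extracted point then takes its source Gaussian's best-pixel
*rendered* colour, so point colours match the final rendered scene.
Gaussians never composited fall back to their DC SH colour, with a
logged count. A near clip of 0.25 m drops Gaussians behind or at the
camera, which on turntable scenes removes background splats that would
otherwise occlude the plant. Per pixel, compositing weights plus the
residual (white-background) transmittance sum to one by construction;
the test suite checks this to 1e-6 and checks the whole contribution
table against an exhaustive per-pixel reimplementation on small images.

Interpretation choices worth stating: "contribution" is the scalar
compositing weight (not per-channel), and the assigned colour is the
final rendered pixel rather than the Gaussian's own view-dependent
colour — the point cloud should look like the renders do.

## Background removal on the trained scene

Turntable capture bakes the static background into the scene. Removal
runs three passes in an order where each pass helps the next:

1. **Size cull** — the conventional "2.5 mm" threshold is dimensionally
   ambiguous between a length and a volume. The default interprets it
   as a cut on the longest 1-SD axis *diameter* (`2 max(s) > 2.5 mm`
   removes); a volume mode (`(4/3) pi s1 s2 s3 > 2.5 mm^3`) is
   selectable. The axis reading is the default because a 2.5 mm^3
   volume cut would also delete legitimate foreground Gaussians,
   whereas large Gaussians are observed to always be background.
2. **Metric crop** — keep centres inside the closed 1 x 1 x 1.5 m box.
3. **k-NN sparsity test** — plant Gaussians are closely compact; for
   each Gaussian the mean distance to its 15 nearest neighbours is
   computed (centres only, single pass) and Gaussians exceeding 3.5 cm
   are removed. Removing the large Gaussians first rarefies the
   background, which is what makes this test effective.

## Cloud cleaning

Cleaning mirrors common practice for reconstructed plant clouds, with
every "1 SD" rule formalised as `statistic > mean + 1 SD` over the
whole cloud (single pass, strict `>`):

- **Statistical outlier removal**: per-point mean distance to its k=20
  nearest neighbours (neighbourhood size is not canonical;
  configurable).
- **Surface-residual filter**: a least-squares plane is fitted to each
  point's neighbours within 5 mm and the point-to-plane distance is
  the residual. A *local* plane per neighbourhood is used rather than
  one global surface, which is ill-defined for a plant. For speed the
  neighbourhood is capped at the 30 nearest points within the radius,
  letting all plane fits batch into one vectorised eigendecomposition;
  points with fewer than 3 neighbours cannot support a fit and are
  kept (logged).
- **Component filter**: connected components of the 5 mm radius graph
  with fewer than 2,000 points are rejected (strict "fewer than"; the
  connectivity radius is not canonical and is configurable).

Manual pot segmentation is out of algorithmic scope; an axis-aligned
exclusion box or label mask can be applied by the caller instead.

## Registration and accuracy metrics

Reconstruction accuracy is the directional mean nearest-neighbour
distance: for each point of cloud A, the Euclidean distance to its
nearest point of B, reported as mean ± SD in millimetres. The two
directions answer different questions (coverage of the ground truth vs
precision of reconstructed points) and are not symmetric. Clouds are
first aligned by point-to-point rigid ICP (nearest-neighbour
correspondences, Kabsch update, identity initialisation since both
frames are metric; no scale). Camera-pose agreement between two pose
sets is the absolute trajectory error: mean distance between
corresponding camera centres after an optional Kabsch alignment
(similarity alignment behind a flag for scale-ambiguous SfM poses),
with a 1.5-mm convergence criterion.

## View planning

Capture radius follows the empirical rule `r = 1.5 x plant height`.
View points are a Fibonacci spiral restricted to an elevation band
(equal-area in `sin(elevation)`, azimuth stepping by the golden angle)
— the underlying capture system's "simple sphere point generation" is
not specified further, and the spiral gives near-equidistant coverage
(nearest-neighbour angular spacing CV < 0.25 at 320 views). Every
optical axis passes through the plant centre with world-z kept upward
in the image. Because the physical camera moves only in the x-z plane,
each view point decomposes into a turntable azimuth — the angle between
the fixed x-axis and the point, mapped to [0, 360) — plus the residual
in-plane camera position; the apex (x = y = 0) gets azimuth 0 by
convention. The train/eval split is "1:8" read as every eighth image
held out (index 0, 8, 16, ... eval), the standard convention that keeps
7/8 of images for training. Poses are written as Instant-NGP-dialect
`transforms.json` (OpenGL camera axes, metric units, top-level
intrinsics); turntable angle and split label ride along under
non-standard keys that other readers ignore.

## Imaging metrics

Foreground masks threshold the BT.601 luma against the white
background (default 240; the source system's threshold is not stated),
apply 3x3 erosion then dilation (defaults one iteration each), and keep
only the largest 8-connected component. PSNR is
`10 log10(255^2 / MSE)` over all pixels and channels, capped at 100 dB
for identical images; masked PSNR averages the squared error only over
mask-true pixels, so a mostly-white background cannot inflate the
score. SSIM/LPIPS are not re-derived here (established implementations
exist; LPIPS additionally needs pretrained CNN weights).

## The synthetic fixture

`synthetic.make_plant_scene` builds a wheat-like toy scene with known
ground truth so the whole pipeline is testable without data downloads:
a vertical stem of ~250 chained thin Gaussians (1-SD lateral axis
0.5 mm, axial 1.2 mm, ~2 mm spacing over 0.5 m), a few arching leaf
chains at the same density, and sparse background clutter in an annulus
at least 10 cm from the plant with at least 8 cm mutual spacing.
Clutter is one third oversized inside the crop box (caught by the size
cull), one third oversized outside it (caught by the crop), and one
third plant-sized inside it (caught only by the k-NN test). The sizes
are deliberate: the largest plant axis diameter (2.4 mm) sits under the
2.5-mm size cull, plant 15-NN averages (~1.8 cm) sit under the 3.5-cm
sparsity threshold, and clutter 15-NN averages (>= 8 cm) sit far above
it — so background removal is complete and plant-lossless *by
construction margins*, and the background-recall test measures the
implementation, not luck. The ground truth is a dense cloud on the
plant Gaussians' 1-SD ellipsoid shells (the sampled cloud concentrates
within 2.5 SD, so agreement below twice the Gaussian thickness is the
right acceptance scale).

What the fixture does **not** emulate: photometric noise, camera
calibration error, splat-training artefacts (floaters, elongated
background Gaussians threading the plant), soft occlusion boundaries,
or realistic wheat morphology. Passing tests therefore demonstrate the
correctness of the algorithms under their stated assumptions, not
field performance on captured scenes.

## Problem sizes and numerical choices

Library defaults keep production scale (10 M points). Tests and the
acceptance script use reduced sizes chosen to exercise every code path
while completing in seconds: point budgets of 10^3–8x10^4, renders of
24–96 px, fixture scenes of ~10^3 Gaussians, 100k–200k draws for the
distributional checks. At the 80k-point budget the end-to-end fixture
run yields a GT-to-cloud mean distance of ~0.9 mm (below the 2-mm
acceptance scale for 1-mm-thick Gaussians).

Other numerical choices: 2D covariance dilation +0.3 px^2
(anti-aliasing, reference-rasteriser convention); per-splat alpha
ceiling 0.99; depth sorting by mean camera depth globally per view (the
standard splat approximation, not exact per-ray ordering); largest-
remainder ties to the lowest index; k-NN queries by KD-tree with exact
brute-force oracles in tests; opacities clipped to
[1e-12, 1 - 1e-12] before the logit when writing PLY so float32 stays
finite; ICP stops on RMS change < 1e-10 or 50 iterations.

## Known limitations

- The renderer is a CPU reference implementation for contribution
  tracking and fixture rendering, not a performance rasteriser.
- Depth sorting per view (not per pixel-ray) can mis-order
  interpenetrating Gaussians, as in standard splat rasterisers.
- The surface filter's neighbour cap slightly biases plane fits in
  very dense neighbourhoods (the nearest 30 within the radius).
- k-NN background removal uses Gaussian centres only and ignores
  extent; a large flat Gaussian overlapping the plant would evade it.
- `absolute_trajectory_error` compares camera centres only;
  orientation error is not measured.
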