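# Methods

This note records the models and procedures the package implements, the
parameters that matter, what the synthetic scenes do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Ruffling-rate quantification

**Model.** Membrane ruffles are transient, fast-moving bright actin
regions; stress fibers and the cell body are (quasi-)static. The temporal
signature, not the intensity, separates them: at each pixel the rolling
temporal median over a ±25-frame window (±50 s at the 2 s frame interval
the movies are acquired at) estimates the static background, and the
percent ratio raw/baseline × 100 puts static signal at exactly 100%
regardless of its brightness. A median is used rather than a mean because
a ruffle visiting a pixel for less than half the window leaves the median
untouched — the estimator is exact, not merely attenuated, under that
condition. The flip side is a hard limitation: any structure present at a
pixel for more than half of the window is absorbed into the baseline and
becomes invisible to the method. This is intrinsic to temporal-median
normalization, not an implementation artifact.

**Window truncation.** At the movie ends the window truncates to the
available frames, so the baseline stays an order statistic of observed
data; reflection padding would duplicate frames and bias the median.

**Ratio guard.** Baselines below `ratio_floor` (default: 10% of the median
foreground intensity, foreground = above the movie's global Otsu
threshold) mark background pixels: the ratio there is set to 0 and
flagged, guarding the division against near-zero denominators. Flagged
pixels can never be segmented as ruffles.

**Ruffle segmentation (multi-scale adaptive thresholding).** Each ratio
frame is smoothed at `scale_sigmas` (default 1, 2, 4 px), each smoothed
image thresholded by a per-tile Otsu (tiles of `tile_px` = 32 px), and the
per-scale masks unioned before removing objects under `min_object_px`
(default 20 px). Two guards make the local thresholding meaningful: a tile
only contributes its Otsu threshold when the split separates a genuinely
brighter class (above-class mean at least `min_tile_contrast` = 50% above
the below-class mean — Otsu always splits a histogram, even pure noise),
and every threshold is floored at `min_excess_percent` = 130%, i.e. a
ruffle candidate must exceed its own baseline by at least 30%. Tiles with
no usable Otsu split (constant tiles, e.g. the interior of a large ruffle,
or noise-only tiles) fall back to the floor. With 5% Gaussian noise the
smoothed ratio stays within a few percent of 100, far below the floor, so
ruffle-free movies score ≈ 0.

**Cell segmentation.** Global Otsu on a spatially smoothed raw frame
(sigma 2 px), hole filling, size filter. A frame is declared cell-free
(empty mask + warning) when the Otsu foreground is not at least
`min_cell_contrast` = 2× brighter than the background — the guard that
distinguishes "no cell" from Otsu's unconditional histogram split. A fixed
`cell_threshold` bypasses Otsu for manually tuned analyses.

**Scoring.** Per frame, 100 × |ruffle ∩ cell| / |cell|; ruffle masks are
intersected with the cell mask because the score is defined relative to
cell area. Frames with an empty cell mask are excluded from the temporal
mean rather than scored 0, so segmentation failures do not dilute the
rate. The analysis pools all cells in the field of view (rates are
per-video).

## Subcellular enrichment

The reporter channel is divided frame-by-frame by the membrane-marker
channel; pixels with membrane signal under `membrane_floor` are excluded
rather than divided. Segmentation runs on the membrane channel (the
marker defines cell extent) at the user-tuned `seg_threshold`; an option
exists to segment the normalized movie instead. The protrusive class is
mask(T1) \ mask(T0), the non-protrusive class mask(T0) ∩ mask(T1);
retracted pixels (T0 only) belong to neither. Class means are taken over
the normalized frame at T1 — the frame where the protrusive class is
defined — with an `average_frames` option to average T0..T1 instead. T1
is a required user input (the frame of maximal protrusion, which in the
emulated optogenetic experiments varied from roughly 100 to 500 s of
activation); `suggest_t1` proposes the frame maximizing new protruded
area as a starting point. Multi-cell fields should be cropped to
single-cell regions before analysis; the package does not track cell
instances.

## 3D spot detection

Processing order: isotropize (trilinear, to the smallest input spacing),
percentile-normalize (0 → 2nd percentile, 1 → 99.8th, clipped), detect
with `skimage.feature.blob_dog` (min_sigma 3, max_sigma 6, threshold 0.01,
geometric scale ladder with ratio 1.6, overlapping detections resolved by
keeping the stronger when spheres of radius σ√3 overlap by more than
50%). The actin-derived cell mask keeps voxels above the upper threshold
of a 3-class Otsu ("the brightest class"), then — in this exact order —
largest connected component, binary closing with a discrete Euclidean
ball of radius 3, hole filling, and erosion with a ball of radius 1. The
order matters (closing before erosion preserves thin connections; a
regression test pins it). Spots whose rounded center voxel falls outside
the mask are discarded. Compartment densities divide in-compartment spot
counts by compartment area; compartment masks (e.g. a manually traced
lamella region) are user-supplied.

## Simplified 3D segmentation

Preprocessing, in order: min-max rescale to [0, 1] and gamma correction
(γ = 0.8 — defined on the rescaled range so arbitrary AU inputs behave
identically), 3×3×3 median filter, isotropization, percentile
normalization (2 / 99.8), and 1/4 isotropic downsampling (trades surface
detail for whole-cell context on large stacks). Each 2D slice of the
x-y, x-z and y-z orthoviews is Otsu-thresholded and intersected with the
0.2 intensity floor; a constant slice is segmented by the floor alone
(the floor acts as a post-mask intersection). The three view volumes are
fused by majority vote (2 of 3 by default) and the largest component
kept, then the mask is nearest-neighbor upsampled to the input grid.

The vote-based fusion and nearest-neighbor upsampling are deliberate
simplifications of published gradient-flow consensus / label-diffusion /
guided-filter pipelines, which live in dedicated tools; on smooth convex
cells the simplification is essentially exact, but fine surface
protrusions below the downsampled voxel size are not recovered, and the
achievable IoU is bounded by the blockiness of the 4× grid (≈ 0.91 for an
ellipsoid of ~30-voxel radius; larger cells do better).

## Scalar readouts

Proliferation is pixel-based, not nucleus-count-based: 100 × EdU⁺ px /
DAPI⁺ px, with absolute thresholds shared across every sample in a
comparison group (an Otsu-based suggestion helper exists, but the chosen
value must then be applied to all compared images). Integrated density
sums over z first, then over the ROI. Relative blot density double-
normalizes to the solvent-control lane and to the loading-control bands.
Lane-profile band density integrates above a straight line drawn between
the profile values at the integration-window endpoints (the manual
lane-plot convention), trapezoid rule at unit sample spacing, clipped at
zero.

## Synthetic scenes: what they emulate, and what they don't

Every generator is a pure function of its spec including the seed, and
ground truth is computed on the noiseless scene before noise is applied,
so truth never depends on the noise realization.

* **Ruffle movies** render a cell as a filled ellipse, stress fibers as
  constant-intensity thick segments, and ruffles as half-disk caps
  attached to the inside of the cell edge — the simplest shape whose area
  is analytically controllable (the cap radius is iteratively adjusted so
  the rasterized area matches the requested fraction of cell area within
  2% despite edge curvature). Caps slide along the edge by their drift
  converted to arc length. `plan_ruffle_events` tiles events back-to-back
  (duration 8 frames, drift 2 px/frame, amplitude equal to the cell
  intensity) so the time-averaged planted fraction equals the target;
  successive events attach at golden-angle increments with a random
  phase. The golden-angle schedule is what keeps every planted ruffle
  *transient at every pixel*: independently random angles occasionally
  revisit the same edge region for most of a median window, which plants
  a quasi-static structure — something a temporal-median method is
  blind to by construction, and not what a ruffle is.
* **Protrusion movies** grow a cell mask from a base to a full shape with
  pixels appearing in distance order (near the base first), membrane
  channel constant on the current mask, reporter = membrane × planted
  per-region ratio, Gaussian noise last.
* **Spot volumes** are an ellipsoidal cell (actin channel) plus isotropic
  3D Gaussians at planted centers (spot channel), with declared
  inside/outside membership and pairwise separation validated.
* **Nuclei fields** are non-overlapping disks placed by rejection
  sampling; EdU positivity is assigned to the first ⌊n·fraction + 0.5⌋
  nuclei in seeded shuffle order, making the positive count exact.

The noise model is additive Gaussian with optional Poisson shot noise on
expected counts — adequate for fluorescence statistics while keeping
truth exact. The scenes deliberately omit point-spread-function blur,
photobleaching, cell motility and shape change, uneven illumination, and
multi-cell crowding. Passing the recovery tests therefore demonstrates
the correctness of the algorithms under the stated statistical structure,
not robustness to every artifact of real acquisitions; on real data the
manually tuned parameters (segmentation thresholds, T0/T1, compartment
outlines) carry that burden, as they do in practice.

## Numerical choices and degenerate inputs

* Intensities are float64 internally; TIFF export is float32 by default,
  with optional min-max 16-bit quantization (scaling recorded in
  metadata).
* Axis conventions: movies T×Y×X, volumes Z×Y×X, 0-based voxel
  coordinates, boolean masks.
* Constant volumes are rejected at percentile normalization (the anchors
  coincide); constant 2D slices in orthoview segmentation fall back to
  the intensity floor.
* Division guards: ratio normalization and membrane normalization
  exclude-and-flag rather than divide by small denominators.
* Empty classes/masks produce NaN plus a structured warning rather than
  silent zeros; all-empty cell masks are a hard error.
* Seeds: every generator consumes a single integer seed via numpy's
  default generator; identical specs give bit-identical arrays.

## Problem sizes used in the validation suite

The test and acceptance scenes use 128×128 movies of 60 frames (24–40 for
unit tests), 64³ spot volumes (20 scenes), a 96³ segmentation volume, and
256×256 nuclei fields with 20 nuclei — sizes chosen so each planted
structure spans enough pixels for stable statistics while the whole
validation run completes in well under a minute on one core.

## Known limitations

* No per-ruffle tracking, kymographs, or 3D ruffle segmentation.
* No automatic per-cell instance segmentation; multi-cell enrichment
  fields need manual cropping.
* No spot intensity quantification or colocalization statistics.
* The 3D consensus is a stand-in: fine protrusion recovery requires the
  dedicated gradient-flow tools it simplifies.
* Proprietary microscope formats (CZI/ND2, OME-Zarr) are out of scope;
  inputs are plain multi-page TIFFs.
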