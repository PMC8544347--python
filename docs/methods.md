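# Methods

This note documents the models, parameter choices and numerical decisions
behind `taphen`, and what the synthetic-data validation does and does not
demonstrate.

## Imaging model and conventions

Images are RGB rasters indexed `(row, col)` with row 0 at top, 0-based and
half-open; the default physical scale is 52 nm/px on a 2560 × 1920 frame
(the camera geometry of the instrument the pipelines were designed for).
8- and 16-bit inputs are processed natively — thresholds are always
computed on the image's own range, never after rescaling. Grayscale
conversion uses the ITU-R BT.601 luma weights (0.2989, 0.5870, 0.1140; sum
0.9999). The camera's true RGB→gray transform is not documented anywhere
authoritative, so BT.601 — the default of the numerical environments these
pipelines historically ran in — is fixed as a package constant.

Masks use 8-connectivity throughout. The published processing constants
state 8-connectivity only for the nucleoid stage; applying it uniformly
keeps all component analyses consistent (a design choice, documented here).

## Thresholding

`otsu_threshold` maximizes the between-class variance of the n-bin
(default 256) histogram over `[min, max]` of the image. Class statistics
use exact per-bin intensity sums rather than bin centers, so the result
coincides with an exhaustive search over the same candidate edges
(validated against a brute-force oracle on random images). Ties resolve to
the lowest qualifying edge; foreground is *strictly greater* than the
threshold; a constant image degenerates to an empty foreground with a
warning. Stain signals that are identically zero yield empty masks rather
than an error, so blank channels flow through batch runs.

## Non-flat top-hat

Background suppression is the white top-hat `f − opening(f, b)` with a
non-flat ellipsoid element `b` (radius R = 60 px, height H = 5):
`h(d) = H·sqrt(1 − (d/R)²)`. Erosion/dilation are the signed non-flat
forms (`min_o f(p+o) − h(o)`, `max_o f(p+o) + h(o)`); borders are padded
by edge replication so flat borders produce no spurious response, and the
output is non-negative because the opening is anti-extensive.

Two kernels implement the operator:

* an **exact dense kernel** (scipy `grey_erosion`/`grey_dilation` with the
  full footprint), used automatically for small problems and validated
  pixel-for-pixel against a direct min/max oracle;
* a **level-decomposed kernel** for production-size frames: the radial
  profile is quantized into 6 evenly spaced heights, giving a stack of
  flat-disk erosions that are evaluated with separable 1-D running
  min/max filters (prefix-doubling sparse tables) in O(levels × radius)
  full-frame passes. This computes the *exact* non-flat morphology of the
  quantized element; the quantized profile deviates from the continuous
  one by at most H/5 = 1 gray level, which is negligible against cell
  amplitudes of 30–200. Both directions share the quantized element, so
  the opening remains a true (idempotent, anti-extensive) opening and
  shift invariance `tophat(f + c) = tophat(f)` holds exactly.

With this decomposition a full 2560 × 1920 channel opens in a few seconds
instead of several minutes, which is what makes whole-frame batch analysis
practical. The membrane pipeline filters channels in float32 — lossless
for integer camera data — to halve memory traffic.

## Extended maxima

`extended_maxima(f, h)` is the classical operator: regional maxima of the
H-maxima transform, computed via grayscale reconstruction by dilation of
`f − h` under `f` (scikit-image's reconstruction) followed by regional
maxima at the configured connectivity. It is validated against an
iterative fixpoint oracle (`g ← min(dilate(g), f)`), both connectivities,
on random images. A constant image is returned as a single whole-frame
component (logged); the edge filter downstream removes it.

Note a consequence of the operator's semantics: a focus of prominence
below h on top of a cell does not vanish — the *cell body* remains the
surviving maximum. Shallow foci therefore produce cell-scale regions, not
focus-scale ones; the focus-suppression tests assert exactly that.

## Region measurement and gating

`measure_regions` wraps scikit-image's `regionprops`: area is the member
pixel count, perimeter the weighted boundary-configuration estimator of
that library (the common practice estimator; the published pixel gates of
165 px and 250 px were tuned for an estimator of this family, and the
suite checks squares of side 10–40 px against 4(s−1) within 10 %).
Labels follow raster-scan order of first pixels. Gating is strict on the
discard side — objects exactly on a boundary are kept — mirroring the
"larger than / lower than / higher than" semantics of the published rules.

Shape descriptors: circularity 4πA/P² and the eccentricity of the ellipse
with equal second central moments. Collinear regions report
`1 − 1e-9` with a warning rather than a hard error.

## Membrane classification details

The EB mask takes priority over the DAPI mask because EB bleeds into the
blue channel while DAPI never appears in red: the blue mask loses every
pixel of the red mask dilated by a flat disk of radius 3 px ("3-px
dilation" is read as a disk radius, not three iterated 3×3 dilations).
Fragments pushed below the 300-px cleanup floor by that subtraction are
removed, so the subtraction cannot mint specks. The published processing
applies the 300-px cleanup *and* a 400-px area gate; both are implemented
as stated even though the first is partially redundant.

## Nucleoid pipeline

Background correction reuses the membrane top-hat (same ellipsoid SE) —
the two stages operate on the same acquisition, so sharing the background
model is the natural reading. Interactive deletion of misidentified
objects is replaced by a reproducible exclusion-list file plus a QC
overlay with labels stamped at centroids; excluded records stay in the
output with a flag so curation is non-destructive.

## AFM registration

The transform model is a pure isotropic similarity (scale, rotation,
translation) — dried cells must not shear, so affine terms are
deliberately unsupported. Estimation is Umeyama least squares on
control-point pairs; the reproducible control-point route replaces
interactive registration tools. An optional automatic mode (grid search
over rotation/scale scored by normalized cross-correlation of gradient
magnitudes, refined by Nelder–Mead) is provided best-effort and always
reports its score. Warping is inverse-mapped bilinear resampling with
zero fill; the draped overlay shades the topography with a Lambertian
model after normalizing the height range to 5 px of relief (heights in nm
and the pixel grid are incommensurate; without normalization any real
cell is rendered as a black cliff). Flat topography reproduces the color
image exactly.

## Synthetic scenes

The generator renders spherocylinder cells (rectangle plus semicircular
caps) of width 0.8 µm and length 1–3 µm at 52 nm/px, hard-edged and
painted opaquely so per-cell area and intensity identities are exact; a
blur flag exists for realism experiments. Membrane-intact cells are
blue-dominant (20, 40, 200), damaged cells red-dominant (200, 30, 0) with
a bleed-through fraction β = 0.2 of the red value into blue — large
enough to exercise the `gray − B` arithmetic, small enough never to flip
a class. Per-cell brightness jitter is ±10 %. The default background is a
flat offset of 10 with optional ramp and smooth blobs; default noise is
Gaussian σ = 2 (shot-like `poisson_like` is available). Cells are placed
without overlap with a 15-px separation margin; edge-touching cells and
3-rod aggregates can be requested to exercise the cleanup and perimeter
gates. Nucleoids are flat-top profiles: condensed, a round
`exp(−(r/7)⁴)` spot of amplitude 100 at the cell centre; diffuse, an
axis-elongated cloud of half the amplitude. With the H-maxima depth of
30 this yields condensed regions of ≈ 100–200 px and diffuse regions
2–3× larger and visibly elongated — the morphometric contrast the
pipeline is meant to detect.

Pipeline presets draw cell lengths so that footprints fall inside the
corresponding published area window (e.g. 1.6–2.9 µm for the membrane
window [400, 2000] px); scenes are otherwise identical across presets.
The AFM pairing renders intact cells as smooth rods of 300 nm peak height
and "deflated" cells at 40 % height with seeded globular debris
(membrane-damaged cells deflate first); cell positions in the height map
are the fluorescence positions pushed through a caller-supplied
similarity transform, which the ground truth records for closed-loop
registration tests.

**What passing these tests shows** — that the implementation computes the
documented operators correctly and that the pipelines invert the
generator's forward model under its assumptions. **What it does not
show** — robustness to point-spread blur, chromatic aberration, uneven
illumination beyond smooth ramps, focal drift, dense colonies, or stain
variability of real micrographs; the generator deliberately omits optics
simulation, photobleaching kinetics and AFM tip convolution.

## Problem sizes

The validation suite uses 640 × 480 scenes (the `--small` preset) with
10–15 cells for per-scene checks, 20 seeds for recovery-rate statistics,
100–200 random draws for estimator accuracy, and one full 2560 × 1920
scene for the end-to-end run — sizes at which every behaviour of the
full-frame pipeline (large-SE top-hat included) is exercised while the
whole suite stays fast.
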