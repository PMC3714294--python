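# Methods

This note documents the models, algorithms and defaults behind `tlmquant`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate about real microscopy data.

## Data model

The pipeline consumes pairs of spatially registered 8-bit grayscale images
per time point — one phase-contrast, one fluorescence — as single-plane
TIFFs, plus acquisition times in hours. Inputs that are not 8-bit are
rejected rather than rescaled: every downstream operation (clamped mask
arithmetic, 0–255 histograms) assumes the 0–255 range, and silent
conversion would change measured values. The data model carries one or
more fluorescence channels, but one channel is processed per invocation.
Registration is assumed; the package performs none.

## Segmentation

The chain is the classic recipe for dark rods on a bright phase-contrast
field, applied per frame:

1. **Rolling-ball background subtraction** (default radius 50 px).
   Cells are dark on a bright background, so by default
   (`light_background=True`) the ball rolls under the *inverted* image and
   cells emerge bright. Two numerical choices matter:
   - the ball rides on a grayscale closing (4 px disk) of the working
     image, so narrow dark dips — the inverted halo rims surrounding each
     cell — are treated as features instead of dragging the illumination
     estimate down, which would otherwise create ring artifacts around
     cells;
   - for radii above 8 px the image is shrunk by a block minimum
     (factor `radius // 8`), the ball rolled on the reduced image, and the
     background upsampled bilinearly. This stays within a few grey levels
     of the exact result at ~1/300 of the cost (≈40 ms instead of ≈4 s per
     512×512 frame).
2. **Sharpening convolution**: 5×5 kernel, center 24, others −1 (sum
   zero), correlated with edge replication and clamped to [0, 255]. A
   sum-zero kernel suppresses flat regions and responds to edges; at 5 px
   cell width every interior pixel is close enough to an edge to respond,
   so whole cells survive thresholding. The kernel is fully overridable —
   it should be adapted to cell type, magnification and exposure.
3. **IsoData (intermeans) threshold**: the returned integer T satisfies
   T = round((mean of pixels ≤ T + mean of pixels > T)/2). It is computed
   as the lowest fixed point of that map over the 256-bin histogram — a
   deterministic, shift-equivariant formulation that avoids any dependence
   on an iteration's starting point. A constant image returns its own
   value, which yields an empty mask under the strict `above` polarity.
   Otsu and a fixed manual threshold are available as configuration
   choices.
4. **Binarization** to a 0/255 mask (cells = pixels strictly above T;
   `below` polarity covers optics where cells land dark after processing).
5. **De-speckling**: one pass of a 3×3 median filter. This removes
   isolated noise pixels and is idempotent on speckle-free masks of solid
   rods.
6. **Particle analysis**: 8-connected components (4-connectivity is a
   config option), filtered to [`min_area`, `max_area`], labelled
   consecutively in scan order. Border particles are kept by default
   (`exclude_edges` drops them).

`min_area` defaults to 40 px: with the default optics the smallest
plausible rod (15 px × 5 px with round caps) covers ~60 px, while the
clumps produced by the sharpening kernel's ~25× noise amplification stay
below ~40 px after de-speckling. Cells in physical contact segment as one
particle by design; population statistics treat such a merged pair as a
single cell, which slightly smooths the intensity distribution in dense
fields.

## Fluorescence quantification

Two measurement paths exist for the fluorescence channel:

- **direct** (default): the arithmetic mean of fluorescence over each
  particle's pixels.
- **inverted** (`--faithful`): the image-calculator scheme. The
  fluorescence image is subtracted from the mask with clamping at 0, so
  background pixels become 0 and every cell pixel becomes 255 − f.
  Selecting all grey values above the minimum (≥ 1) isolates cell pixels,
  and 255 − mean recovers the original intensity. A cell pixel whose
  fluorescence is exactly 255 inverts to 0 and silently drops out of the
  measurement; this clamped-arithmetic quirk is reproduced deliberately,
  and a particle losing *all* pixels that way is flagged invalid rather
  than reported as zero. On particles without saturated pixels the two
  paths agree exactly, which the test suite verifies against each other
  across hundreds of randomized frames.

**Background** is estimated by the complementary trick: fluorescence plus
mask, clamped at 255, saturates every cell pixel; the mean over the
remaining values below 255 is the mean background fluorescence outside the
cells. Background pixels that are themselves 255 are excluded — the same
clamping quirk, kept for fidelity; a mask covering the whole frame is an
error.

**Normalization** defaults to subtraction, `cell mean − background mean`,
keeping intensity units (AU) so that downstream SD-vs-mean analysis
operates on the same scale; slightly negative values for non-expressing
cells are preserved, not clamped. A ratio mode
`(cell − background)/background` is available behind a flag. The mode used
is recorded in the output metadata.

## Heterogeneity and the noise baseline

Per frame, the package reports *n*, mean and sample SD (n−1 denominator;
SD = 0 when n = 1) of the normalized per-cell intensities. Frames with no
valid measurement are skipped with a warning, never written as zero rows.

Even a perfectly homogeneous reporter shows nonzero frame SD — shot noise,
segmentation error, focus and illumination drift — and this floor grows
with mean brightness. The baseline model is a straight line fitted by
ordinary least squares to (mean, SD) points from a homogeneous control
imaged at several induction levels:

`SD = slope · mean + intercept`

The fit is unweighted (each frame counts once regardless of its cell
count; a weight-by-n option exists but is off by default), the intercept
is free, and the fit requires ≥ 3 points spanning a nonzero mean range.
The model is serialized as a standalone JSON artifact so one control
experiment can correct any number of test series. Corrected heterogeneity
is `raw SD − predicted SD`; negative values are reported as-is because
clamping would hide model misfit.

For time-point summaries (bar charts), each requested hour selects the
nearest frame (earlier frame on an exact tie; requests outside the series
span are errors), optionally pooling all frames within a window. Pooled
mean and SD are computed exactly from the per-frame (n, mean, SD)
summaries — identical to the statistics of the concatenated raw values.

Bar charts cannot distinguish highly noisy from bistable expression; the
heatmap can. As a labelled extension beyond the core method, `count_modes`
reports the number of local maxima in a smoothed intensity histogram
(default 16 bins, width-3 boxcar, peaks under 10% of the maximum ignored).
It is a descriptive aid, not a formal bimodality test, and is wrong on
roughly 1 in 50 random draws of the benchmark distributions.

## Visualization

The heatmap grid histograms per-cell normalized intensity per frame into
global bins (default 64 over the observed range; values outside an
explicit range are clipped into the edge bins so every cell is counted
exactly once — column sums equal per-frame cell counts). Color encodes
cells per (time, intensity) bin through an ordered list of
(count upper bound, color) steps read from a two-column CSV (header
optional); counts beyond the last bound saturate to the last color.
Output is PDF or PNG; PDF metadata dates are stripped so identical inputs
produce identical bytes.

## Synthetic data generator

The generator replaces the microscope for testing and calibration. It is
*not* a physical optics simulation; it emulates the image features the
pipeline keys on.

**Growth**: rods (rectangles with semicircular caps, width 5 px) grow
exponentially in length (doubling time 1 h) and divide at 30 px (5%
jitter, floored at 1.02× current length so a fresh cell cannot divide
instantly) into two daughters splitting at the midpoint with 5% asymmetry
jitter. Founder lengths are log-uniform on [15, 30) px — the stationary
age distribution of exponential growth — so founder divisions spread
evenly over the first doubling and a 10-cell field holds ~20 cells after
one doubling time. Founders are placed by rejection sampling with a
capsule-distance criterion (≥ 4 px surface gap), so t = 0 fields are
non-touching by construction; daughters are placed end-to-end along the
mother's axis, so growing microcolonies *do* develop contacts, as real
ones do.

**Expression scenarios** (per-cell intensity in AU, drawn at birth;
daughters inherit the mother's mode; induction coincides with the start of
imaging):

| scenario    | distribution                          | default          |
|-------------|---------------------------------------|------------------|
| homogeneous | one Normal mode                       | N(60, 6²)        |
| noisy       | lognormal, moment-matched to mean/SD  | mean 60, SD 40   |
| bistable    | two Normal modes, founder mode drawn  | N(10, 3²) / N(120, 12²), P(high) = 0.4 |

These values were chosen once as a realistic 8-bit operating point — far
from both the noise floor and saturation for the homogeneous control, a
heavy right tail for the noisy case, and well-separated ON/OFF modes for
the bistable case — and are the conditions under which all benchmarks run.

**Rendering**: phase = bright field (180) with dark rod interiors (60) and
a 1.5 px halo rim (210); halo is painted only outside every cell so
touching cells are never severed by a neighbour's rim. Fluorescence = dim
background (8) plus uniform interior at the cell's true intensity
(1 AU = 1 grey level). Gaussian read noise (SD 3 phase, 2 fluorescence) is
added and values clamp to [0, 255]; the exact per-pixel uint16 label mask
and a truth CSV accompany every frame. Everything is reproducible from a
seed, byte for byte.

What the generator does **not** emulate: phase-contrast optics (PSF, shade
off, halo physics), intracellular intensity gradients, photobleaching,
focus drift, stage jitter, motility, cell curvature or 3-D structure.
Passing benchmarks therefore demonstrate the correctness of the analysis
chain under controlled conditions, not segmentation robustness on
difficult real imagery — on real data the convolution kernel, threshold
method and area filter are expected to need tuning.

**Noise calibration**: `simulate_noise_calibration` emulates the
homogeneous-control induction series directly at the measurement level:
four induction levels (means 20/40/80/160 AU), 134 frames each (536
points), 50 cells per frame, per-cell values Normal with SD following
`0.1·mean + 2`. The OLS fit recovers both parameters within a few percent
with r² ≈ 0.96; sampling noise of a 50-cell SD (se ≈ SD/√(2n)) bounds the
attainable r².

## Problem sizes and benchmarks

The test suite and `scripts/acceptance.py` run end-to-end on: 200
randomized 48×48 frames for the measurement-scheme equivalence; five
512×512 fields of 20–200 non-touching rods for segmentation recovery
(recall and false-positive rate via greedy Jaccard > 0.5 matching against
the label mask); the 536-point calibration plus a held-out 14-frame
homogeneous series for the baseline model (bias < 2·SE, no significant
time trend); five seeds × three scenarios × six frames (40 founders,
512×512) for scenario ordering by corrected heterogeneity; and a 192×192,
5-frame pipeline rerun for bytewise determinism. These sizes were chosen
so the whole suite completes in well under a minute while every statistic
retains enough data to be meaningful.

## Known limitations

- Touching cells are counted as one particle; dense microcolonies
  therefore under-count cells and smooth the intensity distribution.
  Lineage tracking is out of scope.
- The noise baseline is a single pooled straight line; heteroscedasticity
  beyond the linear trend (e.g. at very low means) is not modelled.
- The inverted measurement path inherits the 255-saturation quirk by
  design; use the direct path for new data.
- 8-bit inputs only; no flat-field correction, photobleaching correction
  or absolute calibration.
- The heatmap's count-to-color mapping is piecewise constant by scheme
  design; fine count differences within a band are not visible.
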