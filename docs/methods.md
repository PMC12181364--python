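# Methods

`sweclip` analyses exported shear-wave elastography (SWE) clips in which a
color elastogram is superimposed at 50% opacity on the grayscale B-mode
image. This note describes the models and procedures the package implements,
the choices made where the design was genuinely open, and what the synthetic
test fixtures do and do not establish about real data.

## The display model and its inversion

The device maps Young's modulus E linearly onto a colormap: a pixel showing
the color at normalised position `t = E / E_max` of the color bar, where
`E_max` is the user-set maximum of the elasticity range. The displayed pixel
is then an alpha blend over the underlying B-mode gray `g`:

    display = round(alpha * cmap(E / E_max) + (1 - alpha) * g),   alpha = 0.5

Inverting this is underdetermined per pixel because `g` is unknown. The
decoder therefore searches the finite set of *achievable* blended colors

    { alpha * lut[k] + (1 - alpha) * g :  k = 0..n_lut-1,  g in G }

where `lut` is the colormap discretised at `n_lut = 256` samples and `G` is
a gray grid of step 4 (0, 4, ..., 252, plus the 255 endpoint so the
brightest background is achievable). A pixel is first classified:

* **grayscale** if its channel range is at most `chroma_tol` (default 8) —
  these carry no elasticity value;
* otherwise **colored** if its Euclidean distance to the nearest achievable
  blend is at most `gamut_tol` (default 12), decoding to
  `E_max * k / (n_lut - 1)` for the matched LUT index `k`;
* otherwise **out of gamut** (no value by default; configurable to take the
  nearest match).

The nearest-neighbour search runs on a KD-tree over the achievable set;
duplicate achievable colors are collapsed onto their lowest LUT index and
exact distance ties resolve toward the lower index, so decoding is
deterministic and conservative. The tolerances absorb one unit of channel
rounding plus mild compression noise; both are exposed.

For forward-rendered, rounded pixels the decode error is bounded by LUT
quantisation plus rounding leverage:

    |decoded - E| <= E_max / (n_lut - 1) + 2 * E_max / span

where `span` is the smallest per-channel range of the colormap (255 for the
default map, giving about 3.5 kPa at E_max = 300). The measured worst-case
error over a dense value grid crossed with every 8-bit background gray is
about 1.2 kPa — one LUT step.

### The colormap itself

The vendor's "temperature gradient" map is not published as RGB values. The
default is a six-stop blue → cyan → green → yellow → orange → red map at
uniform positions. Because every adjacent stop pair shares a saturated
channel, the blended sets of different LUT indices never alias, so inversion
is well-posed. When a color-bar region is configured the package prefers
*self-calibration*: `sample_colorbar` reads the displayed bar (median color
per sampled row, interpolated at fractional rows so stop positions stay
uniform), which removes the dependence on undocumented vendor data. A
user-supplied `position,r,g,b` CSV is the third option. Matching is done in
RGB; an opponent/chromaticity space was considered and rejected as an
unverifiable extra assumption.

## Segmentation and physical scale

Exported videos surround the elastogram with an orange line (white for
single-image exports). Automatic segmentation matches frame-line pixels
(orange: R >= 200, 80 <= G <= 180, B <= 80; white: all channels >= 245; both
overridable as center + tolerance), groups them into 8-connected components,
and accepts a component as a ring when at least 90% of its bounding-box
perimeter is matched — this rejects orange glyphs and color-bar segments,
which are either small or solid (a solid block has no interior after line
thickness is removed). The largest valid ring wins; the measured per-side
line thickness is excluded so the returned half-open rectangle is exactly
the elastogram interior. Geometry is detected once on a reference frame
(default the first, configurable) and reused for every frame of the clip.

Millimetre scale comes from the measurement bar: the brightness profile of
the configured ruler band is scanned for local maxima (prominence at least
half the profile range), and `mm_per_px = tick_interval_mm / median
inter-tick spacing`. The tick interval (default 10 mm) is the user's
responsibility since bar formats vary. Both detection failures raise
explicit errors that instruct manual fallback (`manual_box` + `mm_per_px`).

## ROIs and statistics

Two ROI modes exist inside the detected box: a hand-specified rectangle
(given in mm from the box's top-left corner, rasterised by a pixel-centre
rule) and a grid of square cells (default 4 x 4 mm, side
`round(cell_mm / mm_per_px)` px). The grid is anchored at the top-left
corner — deterministic and matching reading order, since no anchor is
otherwise implied — and partial boundary cells are dropped rather than
clipped so all cells are statistically comparable. All pixel rectangles are
half-open; pixel centres belong to at most one region, so shared edges are
never double-counted.

Each frame is decoded and summarised independently — no temporal averaging —
mirroring how clips are displayed. The per-frame statistic vector over the
ROI (and per grid cell) is: the number and percentage of pixels carrying an
elasticity value (the fill percentage, an image-quality proxy), mean,
median, standard deviation (n−1 denominator), interquartile range
(linear-interpolation quantiles), maximum, and the number and percentage of
values exceeding the top 2% of the scale maximum. Conventions fixed for
testability: the "top 2%" threshold is `0.98 * E_max` (the scale maximum is
the only fixed maximum available before statistics are computed; the
per-frame observed maximum is the plausible alternative), and the
percentage's denominator is the valid pixels (configurable to all ROI
pixels). Clip summaries are arithmetic means over frames with at least one
valid pixel; empty frames carry no stiffness information and are excluded,
not imputed. Frames that fail to process are reported and skipped without
aborting the clip.

## Unit conversions

Under incompressible, locally isotropic tissue with density rho
(default 1000 kg/m^3):

    E = 3 * mu,      mu = rho * c^2   =>   c = sqrt(1000 * E_kPa / (3 * rho)) m/s

With the default density this is `c = sqrt(E_kPa / 3)`, which reproduces the
published trapezius MDC conversions (10.23–27.9 kPa Young's modulus ↔
3.41–9.3 kPa shear modulus ↔ 1.85–3.05 m/s SWV) to printed precision. SWV
columns can be emitted alongside kPa (`units="both"`); shear modulus exists
only as a conversion utility, not a reporting unit. NaN (missing statistics)
propagates through all conversions.

## Agreement statistics

`compare_methods` composes the validation workflow on per-clip summary
values from two methods, with the difference convention d = A − B
(algorithm minus reference):

* **Spearman's rho** — Pearson correlation of average ranks; two-sided
  p-value by full permutation enumeration for n <= 10 and the t
  approximation with n − 2 df above that (matching common software at
  study-sized n while staying exact for tiny inputs).
* **Bland–Altman** — bias = mean(d); SD with the n−1 denominator; limits of
  agreement fixed at `bias ± 1.96 * SD` (1.96 by convention, not t-based);
  95% CI of the bias using t with n−1 df (the t/z choice is unstated in
  common descriptions; t is standard practice); percentage of differences
  inside the LoA; and a proportional-bias check by OLS of d on the pair
  means with the slope F-test on (1, n−2) df. The whole branch repeats on
  natural-log-transformed data (the standard recommendation) to separate
  true proportional bias from non-normality. Degenerate inputs are handled
  explicitly: constant differences leave the regression undefined; a perfect
  non-constant fit reports p = 0 with an exact-fit flag.
* **Shieh's exact agreement test** — tests whether the population central
  95% range of differences, `mu -+ gamma * sigma` with
  `gamma = z_{0.975} = 1.959964`, lies inside pre-specified margins
  `(delta_low, delta_high)`. The exact one-sided 1−alpha bounds are

      bound = mean -+ q * sd / sqrt(n),
      q = nct_quantile(1 - alpha; df = n - 1, ncp = sqrt(n) * gamma)

  whose pair forms a 1−2·alpha (default 90%) interval; non-agreement is
  rejected — the methods declared interchangeable — iff both bounds fall
  strictly inside the margins. The margins are a substantive clinical
  choice (e.g. an MDC) with no defensible default, so the test runs only
  when they are supplied. With sd = 0 the bounds collapse to the mean.

Calibration is verified by simulation: the bias CI covers at its nominal 95%
rate (2,000 replicates), the type-I error of the Shieh test at the null
boundary stays at alpha, and the noncentral-t bounds agree with an
independent parametric-simulation oracle (the normal variation of the mean
integrated analytically over 100,000 systematic draws of the sample SD) to
well under 0.01 sigma for n in {10, 50, 200}.

## Synthetic clips: what they emulate and what they do not

The fixture renderer produces the exact layout the analyzer expects: clipped
Gaussian gray noise as the B-mode background (mean 60, SD 25 — chosen to
exercise the decoder across gray levels, not for acoustic realism), the
blended elastogram (rounding half away from zero), the frame line, a ruler
with bright ticks, and a solid color bar whose height is chosen so the
colormap knots land on integer rows. Three field models cover the test
space: `constant`; `gradient` (linear ramp of range `amplitude_kpa`); and
`smooth-random` (Gaussian noise smoothed at a spatial correlation length,
normalised so `amplitude_kpa` is its standard deviation — defaults
120 ± 60 kPa at a 15 px correlation length, a realistic muscle-stiffness
spread on a 300 kPa scale). A per-frame scalar jitter (default SD 5 kPa)
emulates temporal stiffness fluctuation, and a dropout fraction punches
gray holes where the device reports no value. All randomness derives from
one seed through tagged sub-streams, so clips are bit-reproducible; both
writers (PNG stack and uncompressed RGB multi-frame DICOM with
deterministic UIDs) round-trip pixels losslessly.

Passing on these fixtures establishes that the pipeline inverts its own
display model exactly as specified — it does **not** establish robustness to
vendor-specific rendering details (compression artefacts, anti-aliased frame
lines, annotation glyphs overlapping the elastogram, colormaps that differ
from the sampled bar) or to operator error during acquisition. Real exports
should be spot-checked, ideally with the color-bar self-calibration enabled.

## Problem sizes and numerical conventions

The test suite renders compact clips (10 x 16 mm elastograms, 3 frames) and
the acceptance script uses 9 such clips (3 field models x 3 seeds), 10
random segmentation layouts, a 256-value x 256-gray round-trip grid, and
2,000-replicate calibration runs — sizes at which every check is
comfortably stable. Other conventions: channel rounding is half away from
zero; quantiles use linear interpolation between order statistics; SD uses
the n−1 denominator; all boxes are half-open pixel rectangles.

## Known limitations

* Only vertical layouts (elastogram above B-mode) and a single configured
  opacity are supported; free-form ROIs are not.
* The default colormap is an approximation of the vendor's; accuracy on real
  clips depends on color-bar sampling or a user-supplied stop file.
* Devices may apply their own (rounded) internal E ↔ SWV conversion; the
  package uses the standard formula and does not emulate vendor rounding.
* Statistics treat decoded pixel values as exchangeable measurements; no
  spatial correlation model is applied.
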