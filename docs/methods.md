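# Methods

This note documents the models and numerical choices behind `gelquant`:
what each processing stage computes, which parameters matter and why
their defaults are what they are, what the synthetic-gel generator does
and does not emulate, and the known limitations.

## Image model and conventions

A gel image is a rectangular grid of non-negative integers (8- or
16-bit), rows running along the migration direction (row 0 at the
wells), columns across the lanes. All coordinates are 0-based and all
ranges half-open. Only single-channel grayscale images are supported;
stained gels photographed in colour must be converted upstream.

**8-bit reduction.** The optical-density transform is defined on an
8-bit copy. The copy uses *fixed full-range* scaling,
v₈ = round(v₁₆/257), mapping 0→0 and 65535→255 regardless of image
content. Display-oriented software typically rescales by the image's
own display range instead; that makes the OD of a pixel depend on every
other pixel, which is exactly the content dependence a quantification
protocol that forbids brightness/contrast adjustment must avoid. The
mapping is monotone, so band ordering is always preserved.

**Histogram and oversaturation.** The 256-bin histogram spans the
image's own min..max (a constant image degenerates to all counts in the
first bin, edges spanning one gray level). Oversaturation is the
percentage of pixels in the first (black) and last (white) bins; it is
the diagnostic for information loss from over-processing. The automatic
brightness/contrast stretch (off by default; `saturated_fraction`
default 0.35%, the convention of common display software) exists so its
effect on these numbers can be measured, not for quantification.

## Rolling-ball background subtraction

For a light-background gel the image is inverted to a working image
W = (2^depth − 1) − pixels, so bands become bright peaks on a dark
floor. The background is the grayscale opening of W with the half-ball
structuring element h(i,j) = √(r² − i² − j²): an erosion
min_{(i,j)} [W(x+i, y+j) − h(i,j)] followed by the matching dilation.
The corrected working image W − opening(W) is non-negative by
anti-extensivity; mapped back, the corrected gel has a white background
with dark bands preserved.

Choices worth knowing:

* **Exact ball, no approximation.** The opening is computed with the
  true half-ball at any radius (a vectorized sweep over the ball's
  support, clipped to the image extents). Widely used densitometry
  software approximates large balls by a paraboloid on a shrunken
  image; absolute background values can therefore differ slightly from
  such software, while the protocol-level behaviour (radius
  monotonicity, band-area preservation, linearity) is identical. The
  exact formulation is what makes a bit-exact brute-force oracle test
  possible.
* **Edges.** The structuring element's support is clipped at the image
  borders; no padding value is invented, and corners are treated
  symmetrically.
* **Radius.** Default 250 px — large enough that bands (widths of a few
  tens of pixels) cannot be entered by the ball, small enough to track
  illumination drift. The radius is in pixels *and* intensity counts
  (the ball's apex height equals the radius), so on 16-bit images the
  ball follows only gentle intensity relief; this is intentional for
  background, which is smooth by assumption.
* **Monotonicity.** Background estimated at radius 250 ≤ 150 ≤ 50
  pointwise on smooth-background gels: a larger internally tangent ball
  cannot reach deeper into a valley than a smaller one. The test suite
  asserts this pointwise (with a 10⁻⁹ float guard).
* A re-run of the subtraction on its own output removes essentially
  nothing: the opening itself is exactly idempotent (up to float
  associativity), and the corrected image loses at most ~0.1% of the
  dynamic range at band tails where the ball can follow the flanks.

An optional downsampling for very large radii was considered and
rejected: at the image sizes this package targets the exact opening at
radius 250 runs in seconds.

## Lane profiles and peak integration

A lane profile averages pixels laterally over a fixed-width selection
(default 16 px; a warning fires when this is under 30% of a declared
well width, following standard densitometry guidance). Two modes:

* **grayscale** — the raw mean pixel value per row;
* **uncalibrated OD** — OD = log₁₀(255 / max(v₈, 1)) applied *per
  pixel* before averaging. The transform is nonlinear, so order
  matters; transform-then-average is the default (each pixel is an
  independent stain-density sample), and the alternative
  average-then-transform (`od_of_mean`) is provided. The two agree
  exactly on laterally uniform bands, and the acceptance fixtures are
  insensitive to the choice. Pixel value 0 is clamped to 1, bounding OD
  at log₁₀ 255 ≈ 2.407 — the monotone, finite completion of the
  formula at the 8-bit floor.

A peak is integrated above the straight line joining the profile values
at its two boundary positions (the digital equivalent of the manual
ruler-drawn baseline). Negative excursions below the baseline are
clipped to zero: a manual baseline touches the profile at both ends, so
dips below it are noise. Area is the inclusive sum over
[left, right] in pixel·AU; max intensity and the area-weighted centroid
are computed on the same baseline-subtracted signal. Automatic peak
finding (prominence ≥ 5% of the profile's dynamic range, bounds at
flanking minima) is a convenience for exploration; quantitative runs
use explicit bounds.

## Calibration and quantification

**Zero-intercept regression.** The calibration model is A = slope·P
through the origin (no stain, no signal): slope = ΣAP/ΣP²,
SE = √(Σr²/((n−1)·ΣP²)) with n−1 degrees of freedom, the uncentred
R² = 1 − Σr²/ΣA², and a two-sided t-test of slope/SE. These are the
standard through-origin conventions (cross-checked against
no-intercept OLS in statsmodels), chosen so reported slope/σ/R²/p
tables are interpretable.

A caveat the tests make explicit: when band noise is *proportional*
(constant CV), the residual-based slope SE is anti-conservative,
because the largest load dominates the leverage (w = P²/ΣP²) and its
residual is self-fitted toward zero. For a 5-point series spanning 30×,
the estimator's true sampling SE under CV-type noise is
s·cv·√(ΣP⁴)/ΣP² — about 4.6× the regression SE. Slope-recovery checks
therefore compare against the sampling SE; the regression SE is still
the right number to *report* alongside a fit, as standard software
does.

**Single-point marker calibration.** slope = area(reference band) /
(load_ng_per_10µl · V/10), default reference 50 kDa at 750 ng per 10 µl
lane. SE, R² and p are undefined for one point and are reported as
`None` rather than fabricated. A multi-point alternative fits all
marker bands with manufacturer-stated loads (100, 50, 20 kDa). Bands
without a stated load refuse to anchor a calibration.

**Molecular weight.** Piecewise-linear interpolation of log₁₀(MW)
against marker band centroids — the standard semi-log migration law
applied locally, so it is exact at every marker band regardless of how
the gel deviates from global log-linearity. Positions outside the
marker span extrapolate from the nearest segment with a warning. A
global log-linear fit is available as an alternative.

**Wet-lab arithmetic.** Beer–Lambert concentrations
(C = A₂₈₀/(ε₁% · l), ×10 to mg/ml), mixture concentrations by volume
weighting, per-well loads P = C·V·d·1000 ng (d = ½ for the 1:1 Laemmli
dilution; the ×1000 bridges mg/ml·µl to ng), and eluate→culture
back-calculation by mass conservation, Σ(CᵢVᵢ)/V_sample.

## The synthetic-gel generator

The generator emulates the statistical structure the protocol assumes,
not electrophoresis physics. Bands compose **additively in OD** and
attenuate the background multiplicatively:
pixels = bg · 10^(−Σ OD_band), each band a Gaussian along migration
(default σ = 3.5 rows) with a smooth lateral plateau. Consequently the
baseline-subtracted OD-profile area of a band equals
load_ng × response_au_per_ng analytically — the linearity the
calibration model assumes is true by construction, which is what makes
round-trip tests meaningful. (Composing bands additively in pixel
space instead would make OD areas nonlinear in load by roughly
1.15 × peak-OD relative — several percent at realistic amplitudes —
conflating generator artifacts with pipeline error.)

Parameters and defaults:

* `response_au_per_ng` = 0.007 OD·px/ng: puts the 750 ng reference band
  near peak OD 0.6 — strongly stained but far from saturation.
* `background_level` defaults to full white. A non-white background or
  a `background_gradient` (counts/row) adds a smooth drift for
  background-subtraction tests; note that subtracting background in
  intensity space cannot perfectly linearize OD when the background is
  grey (the residual offset compresses the log), so gradient fixtures
  keep the drift gentle (≈ −2 counts/row over ~500 rows, a ~1.6%
  intensity drift), where the residual distortion stays inside the
  generator's stated 2% area tolerance.
* A ±2% antisymmetric lateral tilt across each band's plateau averages
  to exactly 1 over a centred 16 px lane selection (areas unchanged)
  while dithering integer quantization across the averaged columns;
  without it, all 16 columns round identically and quantization noise
  is 4× larger.
* Noise: `noise_sd` (additive Gaussian pixel noise) and `amplitude_cv`
  (per-band multiplicative response scatter, emulating staining
  variability). Both default to 0; identical seeds give bit-identical
  images.
* The marker fixture places ten bands (250..10 kDa) linearly in
  log₁₀(MW) down the lane, with manufacturer loads where stated
  (750 ng at 50 kDa, 150 ng at 100 and 20 kDa, per 10 µl, scaled
  linearly with volume) and *placeholder* loads elsewhere (450 ng for
  the 3× reference bands 75/25 kDa, 150 ng otherwise), flagged
  `quantitative = False` so no test or calibration can treat them as
  ground truth.

What the generator does **not** emulate — and what passing tests
therefore do not show about real gels: band smiling and lane
distortion, overloading saturation, dye-front artifacts, spatially
correlated staining texture, protein-dependent dye binding (real slopes
differ per protein; the generator's response is protein-independent),
and camera physics (Poisson shot noise, flat-field error). Results on
real images depend on those factors and on manual choices (lane
placement, peak bounds) that the synthetic fixtures idealize.

## Problem sizes and determinism

Test and acceptance fixtures use lane-sized images (hundreds of rows,
tens of columns per lane), where the exact radius-250 opening runs in a
few seconds; the dilution series uses 5 lanes in one ~120×270 image.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; pipelines re-run bit-identically, and the
CLI records every processing choice (radius, B&C, OD convention, crop,
seed) in the run metadata.

## Known limitations

* Quantification inherits the manufacturer's tolerance on the marker
  loads; the single-point slope has no finite-sample uncertainty
  estimate by construction.
* OD linearity degrades for bands approaching the 8-bit floor
  (peak OD ≳ 1.5) and for gels with heavy residual grey background
  after subtraction (log-offset compression, see above).
* The rolling ball treats intensity counts as commensurate with pixels
  via the ball height; radically different image scalings (e.g. 8-bit
  vs 16-bit of the same gel) remove slightly different backgrounds at
  the same nominal radius.
* No automatic lane detection: lane centres and peak bounds are inputs,
  as in the manual workflow this package reproduces.
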