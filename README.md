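# gelquant

Protein band quantification from SDS-PAGE gel images by densitometry,
calibrated against the molecular-weight marker as the sole mass standard.

Coomassie-stained gels are routinely photographed to *check* protein purity;
this package implements a protocol that also *quantifies* the bands — without
running a dedicated standard curve on every gel. The molecular-weight marker
ladder, whose 50 kDa band carries a manufacturer-stated 750 ng per 10 µl lane,
doubles as an internal mass standard, so any band on the gel can be converted
to nanograms and an apparent molecular weight in one pass. The intended users
are protein-production and purification labs (e.g. periplasmic nanobody
expression monitored across bioreactor time points) that need titers from the
gels they already run.

## The method

Starting from a single-channel 16-bit TIFF of a stained gel:

1. **Crop** to the region of interest. No brightness/contrast adjustment is
   applied for quantification (the automatic stretch is implemented only to
   measure its damaging effect on the histogram).
2. **Rolling-ball background subtraction** (radius 250 px): the background is
   the grayscale morphological opening of the working image with a half-ball
   structuring element h(i,j) = √(r² − i² − j²) — conceptually a sphere rolled
   beneath the intensity surface. Bands narrower than the ball survive;
   smooth drift is removed. Larger radii remove less background.
3. **Lane profiles** in uncalibrated optical density,
   OD = log₁₀(255 / v₈), computed per pixel on a fixed-scale 8-bit copy
   (v₈ = round(v₁₆/257)) and averaged over a 16 px-wide lane selection.
4. **Peak areas** above a straight baseline drawn between each band's
   boundary points (units pixel·AU).
5. **Calibration** by zero-intercept least squares, A = slope·P, between
   area A and protein load P (ng): either a multi-point dilution-series fit
   (with slope SE, uncentred R², and a t-test p-value) or a single-point
   anchor on the marker's 50 kDa reference band. Unknown loads are
   area/slope; molecular weights are interpolated piecewise-linearly in
   log₁₀(MW) against the marker band centroids.

A seeded synthetic-gel generator (`gelquant.synthetic`) renders gels whose
band OD areas are proportional to load by construction, with ground-truth
tables, so the whole chain is testable without any scanned gel.

## Worked example

`examples/03_marker_quantification.py` builds a two-lane synthetic gel — a
10 µl marker lane plus a "sample" lane carrying a single 31 kDa band of
300 ng — and runs the default protocol end to end:

```
single-point calibration: slope = 0.00700 pixel*AU/ng (50 kDa reference band area over 750 ng)
unknown band: 300.0 ng at 31.0 kDa (ground truth: 300 ng, 31 kDa)

reference-to-neighbour intensity ratios (manufacturer expectation ~3x):
  75 kDa: 2.99x by max intensity, 3.00x by area
  50 kDa: 5.01x by max intensity, 5.00x by area
  25 kDa: 3.00x by max intensity, 3.00x by area
```

The slope is the 50 kDa band's measured area divided by its 750 ng load; the
unknown's area divided by that slope returns its load, and its centroid
position interpolated on the marker ladder returns its size. The other
examples cover simulation and histogram diagnostics (`01`), background
subtraction and peak integration (`02`), and the concentration/regression
arithmetic around the gel (`04`).

A thin CLI wraps the same library calls:

```bash
gelquant simulate spec.json --output-dir out/   # synthetic gel + ground truth
gelquant analyze run.yaml                       # peak table + oversaturation
gelquant quantify run.yaml                      # ng + kDa per band
```

Run configurations (JSON or YAML) default to the selected protocol: radius
250, no brightness/contrast, OD profiles, 50 kDa reference.

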