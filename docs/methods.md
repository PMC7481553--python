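# Methods

## Geometry and conventions

The flow axis runs along image rows (bands horizontal, row 0 at the
top); all coordinates are 0-based with half-open intervals.  Batch
photographs of several well-aligned strips are split into equal-width
vertical lanes, the leftmost `width mod n_lanes` lanes receiving one
extra column so the lanes tile the image exactly.  A lane's intensity
profile is the arithmetic mean of each pixel row.  A band's AUC is the
plain sum of per-row profile values over the band window (rectangle
rule); no trapezoid correction is applied, matching how densitometric
"area under the curve" is normally accumulated over discrete scan lines.

Colour images are collapsed to one analysis plane before any
quantification: per-channel selection for emission-filtered captures
(the signal of a filtered image lives in one channel), or BT.601
integer luminance (0.299/0.587/0.114, rounded) as a fallback.  Pixel
values are assumed linear; no gamma or display adjustment is ever
applied before measurement.

## Band location

Profiles are smoothed with a centred moving average (odd window,
default 5 rows, reflected edges).  Local maxima are ranked by peak
prominence (`scipy.signal.find_peaks`); the `expected_n` most prominent
peaks are kept (ties resolve to the topmost).  Each window grows
outward from its peak until the smoothed profile falls below
`baseline + 0.10 · (peak − baseline)`; the baseline under the peak is
interpolated linearly between the two prominence bases (so a tilted
membrane background yields the band-local level, not the ramp's low
end), growth never crosses the bases, and overlapping windows are
clipped at the midpoint between peaks.  By default the bottom-most band
is labelled `control`, the others `test`.

Batch quantification defaults to **consensus windows**: the flow-axis
profiles of all lanes of one channel are averaged, bands are located
once on that mean profile, and every lane is measured at the shared
windows.  Strips of one batch are aligned by construction, and the
calibrant lanes dominate the mean profile, so blanks — which have no
test band of their own — are still measured at the true test-line
position.  Per-lane detection (`band_location="per_lane"`) remains
available for unaligned inputs, but on a blank lane it can rank the
control line as the first band, which corrupts blank statistics; this
is why consensus is the default.

## Background correction

The background under a band is estimated locally: Otsu's threshold is
computed over the exact value histogram of the band window plus a
flanking margin (2 × window length on each side, clipped to the lane),
with the convention foreground = values ≥ threshold and ties broken
toward the smallest threshold.  The background level is the **median**
of the sub-threshold class.  The median rather than the mean is
deliberate: the sub-threshold class always contains band-tail pixels,
which pull the class mean up by several digital numbers under bright
bands, and under read noise the threshold truncates the background
distribution from above, which biases the mean low; the class median
sits at the membrane level in both regimes (`background_stat="mean"` is
available).  Corrected AUC sums `max(rowMean − background, 0)` over the
window; flooring negative residuals keeps noise from cancelling faint
bands.  If all context pixels are identical Otsu is undefined; the
window is then treated as pure background (corrected AUC 0, warning).

Because the window stops at 10% of peak height, the corrected AUC
captures ≈ 97% of a Gaussian band's analytic mass.  Recovery checks
therefore compare against the analytic Gaussian sum *over the detected
window*, and the simulator's truth slope for calibration recovery is
`response_slope × Σ exp(−k²/2σ²)` over the nominal window
`|k| ≤ σ√(2 ln 10)`.  Against the full-mass Gaussian sum the readout is
systematically ~3–5% low; that is a windowing convention, not an
estimation error.

## Calibration and key measures

Technical replicates are averaged per (analyte, channel, replicate
group) with the n−1 standard deviation (singletons get sd 0 and a
warning), and the calibration line is fitted by OLS (statsmodels) on
the replicate means — signal on concentration, the classic calibration
direction — requiring at least three distinct levels.  Optional
1/concentration weights are available for heteroscedastic data.
`residual_sd = √(SS_res/(n−2))`; R² is the ordinary coefficient of
determination.  Saturated measurements are excluded from fitting by
default because clipped, flat-topped peaks under-report AUC.

Detection limits use the standard blank-based formula set
(`definitions_id = "blank_1645_10sd"`): in signal units
LOB = mean_b + 1.645·sd_b, LOD = LOB + 1.645·sd_low (sd of the lowest
non-blank calibrant, falling back to sd_b when absent), LOQ =
mean_b + 10·sd_b, each converted to concentration by inverse prediction
`(signal − intercept)/slope`.  A limit below zero concentration — which
happens when the blank signal sits below the fitted intercept — is
reported as the label `Negative` rather than a negative number.  The
identifier makes the formula set explicit and replaceable.

## Synthetic strips

The simulator renders what an emission-filtered CCD capture of a strip
looks like: noise-free signal
`background + gradient·row + Σ amplitude_i · exp(−(row−center_i)²/2σ²)`,
uniform across the strip width, optional Gaussian optical blur, additive
Gaussian read noise, rounding to integer pixels, and either saturation
clipping at `2^depth − 1` or a hard error on overflow.  Defaults: 120 ×
24 px strips, test line at row 40, control at row 90, band σ 3 px
(≈ 1 mm lines at ≈ 5 px/mm), 8-bit depth with low background for single
strips; the experiment presets use a 16-bit sensor with background 200
and read noise 2% of the largest test-band amplitude.  Noise is purely
additive Gaussian (imager read noise); Poisson shot noise, membrane
texture and wicking kinetics are deliberately not modelled, so passing
tests demonstrate correctness of the measurement chain, not robustness
to every real-world artefact.

A duplex experiment pairs a green and a red capture per strip: analyte
A reads out in green, analyte B in red, the test-line amplitude follows
each analyte's response function (linear, or a saturating Langmuir
isotherm `amax·c/(k_half + c)`), the control line has a fixed amplitude,
and `crosstalk` optionally leaks a fraction of the other channel's
amplitude into a capture (0 = ideal emission filters).  Per-capture
seeds derive deterministically from the master seed
(`seed + 2·strip_index` for green, `+1` for red), so the two photographs
of one strip carry independent but reproducible noise and identical
designs regenerate bit-identical images.  Two presets cover the common
designs: `sandwich_preset` (both analytes 0–20 units over 5 levels,
linear responses, comparable intensities) and `clinical_preset`
(analyte A 0–1000 nM, an acute-phase-protein range; analyte B 0–60 pM,
a cytokine range; Langmuir responses).

## Numerical choices and edge cases

* Otsu thresholds are integers over the observed values, computed from
  cumulative histogram moments — exact, no binning; ties take the
  smallest threshold.  An all-constant input raises a degenerate-input
  error.
* Equal-prominence peaks keep the topmost first; Otsu-degenerate band
  contexts fall back to "everything is background" with a warning.
* Saturation flagging uses a strict `fraction > threshold` comparison
  (default threshold 0.1% of pixels).
* Reports contain no timestamps or hostnames and matplotlib's PNG
  `Software` tag is pinned, so identical inputs render byte-identical
  documents.
* CLI exit codes: 0 success, 1 usage/configuration, 2 data/processing;
  warnings go to standard error and are never silently suppressed.

## Problem sizes in the test bench

The bundled study uses compact strips (120 × 24 px) and small designs —
5–6 concentration levels × 3 replicates (15–18 strips, 30–36 captures)
per experiment, 100 seeds for slope-recovery statistics, 500 simulated
blanks and 500 spiked strips for the operational LOD check, and 50
seeds per arm for the duplex non-interference comparison.  These sizes
give stable statistics (slope SD ≈ 0.4% of truth across seeds) while a
full test run stays fast.

## Known limitations

* Integer quantization bounds what any reader can recover from faint
  bands: a noise-free amplitude-10 band on background 50 loses ≈ 4% of
  its analytic AUC to rounding before measurement begins, because the
  fractional parts of the band profile are destroyed uniformly across
  the strip width.  Brighter bands (amplitude ≥ 50) recover within
  0.4%.
* Only linear-in-parameters calibration models are provided; saturating
  (4PL/5PL) calibration is out of scope, so strongly curved responses
  should be calibrated over a restricted range.
* Lane splitting assumes well-aligned, equally wide strips; skew and
  rotation beyond a global 90° rotate flag are not corrected.
* The blank-based limit formulas assume approximately Gaussian blank
  noise; the operational LOD check (≤ 10% of strips at the LOD reading
  below the LOB) verifies the consequence, not the assumption.
* The background under a band is a single scalar per band; on a tilted
  membrane (non-zero gradient) the Otsu class median sits near the
  context midpoint rather than the band-local level, costing roughly
  5–10% of the AUC at gradients of 0.2–0.5 intensity units per row.
  Band windows themselves stay band-local under such gradients.
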