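# Methods

## Measurement model

The package treats a macular EDI-OCT acquisition as an ordered stack of N
parallel B-scans (standard N = 31, inter-scan spacing T a single scalar per
volume, typically 233–244 µm) with per-pixel scales `scale_x` (lateral) and
`scale_y` (axial) in mm/pixel. Because scanners report these scales
per-acquisition and they differ across devices and modes, they are
mandatory metadata rather than defaults. Acquisitions below a
signal-strength floor (default 20) are excluded before measurement.

The choroid on each scan is the band between the RPE–Bruch's complex
(upper) and the choroid–scleral interface (lower), supplied as per-column
row indices. The ROI convention is half-open — `upper ≤ row < lower` — so
the per-column pixel count equals the boundary difference exactly, and a
degenerate `upper == lower` column contributes nothing.

### Binarisation

Luminal pixels are classified by Niblack's local threshold
`t = μ_W + k·σ_W − c` computed over a square window of side
`2·window_radius + 1` on the full (unmasked) 8-bit image, so window
statistics near the ROI border reflect whole-scan context. Defaults are
window_radius = 15, k = 0.2, c = 0 — the common ImageJ Auto Local Threshold
settings; all three are recorded in every output record. Choices where the
convention is genuinely open, each fixed and documented:

- border windows use replicate (edge) padding;
- σ is the population (divide-by-n) standard deviation, switchable to n−1;
- "dark" means strictly below threshold, so ties go to stroma and a
  perfectly uniform region yields no luminal pixels (with c = 0 no pixel is
  strictly below its own window mean);
- 16-bit inputs are linearly min–max rescaled to 8 bits before thresholding.

Absolute CVI values do depend on the window and k; the validation strategy
therefore rests on recoverable synthetic ground truth rather than on
matching any cohort's absolute means.

### Areas, volumes, CVI

Pixel counts become areas via `Area = count · scale_x · scale_y` (mm²).
Volumes sum the N−1 inter-scan slabs, each the mean of its two bounding
areas times the spacing; the spacing is converted from µm to mm first so
volumes are true mm³. This is exactly trapezoidal quadrature of the
piecewise-linear area profile, and the implementation is tested to 1e-12
relative agreement against generic `numpy.trapezoid`. CVI ratios are
scale-invariant (the scales and spacing cancel), which the tests assert
directly.

Regional 3D CVI uses the superior 10 / central 11 / inferior 10 split of a
31-scan volume, with scan 1 the superior-most scan. Each region integrates
only the slabs interior to its own block (10 scans → 9 slabs); boundary
slabs are not shared across regions. The whole-macula value integrates all
31 scans as one series, not the sum of the three regions. Scan-count
subsets (11/21/31) are centred on the foveal scan, which defaults to scan
16 of 31 by symmetry; both choices are configurable.

Choroidal thickness is `(lower − upper)·scale_y·1000` µm per column; SFCT
averages the foveal scan's thickness within ±0.5 mm of the fovea column — a
1-D stand-in for the ETDRS central subfield (the full nine-subfield map is
out of scope).

## Statistics layer

- **COV** = 100·SD/mean, reported to 2 decimals (full precision available).
- **ICC(2,1)**: two-way random effects, absolute agreement, single
  measurement, from the ANOVA mean squares
  `(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`; the 95% CI is the
  F-based interval with Satterthwaite degrees of freedom. The absolute-
  agreement form penalises systematic rater offsets through the MSC term
  (tested). Qualitative bands: <0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good,
  >0.9 excellent. Cross-checked against `pingouin.intraclass_corr` in the
  test suite; the implementation itself is independent.
- **Bland–Altman**: mean difference with t-based CI and limits of agreement
  mean ± 1.96·SD (n−1 SD). The identity mean_diff = mean(x) − mean(y) is
  asserted to 1e-12 and is what ties per-region mean differences to the
  overall means.
- **Variance F-test**: F = s²_x/s²_y with two-sided
  p = 2·min(P(F≤f), P(F≥f)) (sidedness is a documented choice).
- **Regression**: per-predictor univariate OLS (categoricals expanded to
  indicator contrasts; reference level is "Chinese" for ethnicity and the
  most frequent level otherwise), then a multivariable OLS on age plus all
  predictors with any univariate term p < 0.05 (age is always retained; if
  nothing passes, the model is outcome ~ age). Fits use statsmodels;
  constant predictors are flagged and excluded, rank-deficient designs
  rejected with the offending columns named.
- **Group comparisons**: one-way ANOVA for continuous variables, Pearson
  chi-square without continuity correction for categorical ones.
- **Quintile-stratified sampling**: split at the 20/40/60/80th percentiles
  (inclusive linear interpolation), boundary ties to the lower stratum,
  then a seeded uniform draw without replacement per stratum.
- Normality testing (Shapiro–Wilk) is omitted: it feeds no downstream
  decision in this pipeline. No multiple-testing correction is applied.

## Synthetic data

`generate_phantom_volume` emulates the acquisition geometry: a flat choroid
band of bright stroma (default 220) at a configurable depth and thickness
(default 288 µm; per-scan profiles can span the ~175–411 µm range of a
thin-to-pachychoroid population), filled with dark elliptical lumina
(default level 30, semi-axes 2–6 px) placed by rejection sampling until
each scan's luminal fraction is within ±0.005 of the target. The
ground-truth masks are captured **before** noise, so |estimated − target|
isolates binarisation error, and the boundary tables are emitted exactly as
constructed. Noise is additive Gaussian plus a multiplicative Rayleigh
speckle component mixed with weight `speckle` — a pragmatic stand-in for
OCT texture, not a physical speckle/PSF model. Cosmetic retina/RPE bands
above the choroid never enter any computation. `identical_scans=True`
reuses one lumen layout on every scan, making the per-scan fraction exactly
constant; this is the configuration used to verify that regional integrals
agree with the whole-macula value, since per-scan placement jitter (±0.5
points) would otherwise dominate that comparison.

What the phantom deliberately does not model: curved or irregular choroid
boundaries, vessel anisotropy and branching, depth-dependent signal decay,
segmentation error. Passing recovery tests therefore demonstrates
correctness of the measurement chain given correct boundaries, not
robustness to segmentation failure on real scans. One visible consequence:
phantom cohorts have essentially homogeneous vascularity across the volume,
so inter-region ICCs on simulated cohorts are near 1 — real eyes, with
genuine topographic variation, give the moderate ICCs the method is
designed to quantify.

`generate_cohort` draws per-eye records around published overall moments
(3D CVI whole 62.92 ± 1.57%, central 63.35 ± 1.72%, 2D subfoveal
63.53 ± 2.09%, SFCT 288.3 ± 85.6 µm, and 11/21/31-subset means derived from
the published pairwise mean differences), correlating CVI measures through
a shared latent factor (ρ = 0.7), plus a standard ocular/systemic covariate
battery. With no injected effects every covariate is independent of every
outcome (a null cohort for calibration); injected effects are mean-centred
linear terms so the outcome's marginal mean is preserved.

## Problem sizes and numerical notes

Default phantoms are 256×512 px × 31 scans — enough for ~500 lumen ellipses
per scan and stable window statistics at radius 15 while keeping a full
phantom under a second to generate and measure. Calibration experiments use
50-eye cohorts with 1000 null replicates (type-I error of the screen) and
200 effect replicates (selection rate), sizes at which the binomial 99%
band around α = 0.05 is ±0.018. All generators and samplers take explicit
seeds; reruns are byte-identical. Degenerate inputs fail loudly: empty
ROIs warn and return empty masks, zero total area/volume raises an
undefined-value error, single-scan volumes cannot be integrated, and
boundary tables violating `upper ≤ lower` are rejected on construction.
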