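# cvi3d — 3D choroidal vascularity index from EDI-OCT volume scans

The choroid, the vascular layer between the RPE–Bruch's membrane complex and
the choroid–scleral interface, is routinely summarised by its thickness —
but thickness ignores the split between vessel lumina and stroma. The
**choroidal vascularity index (CVI)** is the luminal fraction of the
choroid: in 2D the luminal area over the total choroidal area of one B-scan,
in 3D the luminal volume over the total choroidal volume of a macular volume
scan. This package implements the full 3D CVI measurement chain for
enhanced-depth-imaging OCT (EDI-OCT) volumes, the agreement statistics used
to compare 2D against 3D and different scanning volumes against each other,
and seeded synthetic phantom/cohort generators with exact ground truth, so
the whole pipeline is testable without any scanner data. It is aimed at
ocular-imaging researchers who want a reproducible, scriptable alternative
to manual ImageJ workflows.

## Method

For each B-scan, the choroid ROI is the band between the segmented upper
boundary u(c) and lower boundary l(c) (`upper ≤ row < lower` per column).
Luminal (dark) pixels inside the ROI are selected by **Niblack local
thresholding** on the 8-bit image:

    t(r,c) = μ_W(r,c) + k · σ_W(r,c) − c₀,     pixel luminal ⇔ I(r,c) < t(r,c)

with window side 2·radius+1 (default radius 15, k = 0.2, c₀ = 0), replicate
border padding and population σ. Pixel counts become areas via the scanner
scales, Area = count · scale_x · scale_y [mm²], and the per-scan area
profile becomes a volume by summing inter-scan slabs:

    Vol_total = Σₙ (Areaₙ + Areaₙ₊₁)/2 · T,   T = inter-scan spacing in mm

(trapezoidal quadrature). Then

    3D CVI = 100 · LV / TCV   [%],    2D CVI = 100 · LA / TCA   [%].

A standard 31-scan volume is split into superior (scans 1–10), central
(11–21) and inferior (22–31) regions, each integrated over its own interior
slabs, and into fovea-centred 11/21/31-scan subsets. Choroidal thickness is
(l − u)·scale_y per column; SFCT averages the foveal scan within ±0.5 mm of
the fovea column.

The statistics layer provides the coefficient of variation (100·SD/mean),
ICC(2,1) (two-way random effects, absolute agreement, single measurement,
F-based 95% CI), Bland–Altman mean difference and 95% limits of agreement,
the two-sided F-test of variance equality, one-way ANOVA / chi-square group
comparisons, a univariate OLS screen feeding a multivariable model (age plus
all predictors with univariate p < 0.05), and quintile-stratified sampling.

## Worked example

Generate a 31-scan phantom with a known 60% luminal fraction and measure it:

```python
from cvi3d import BinarisationParams, PhantomSpec, generate_phantom_volume, measure_eye

spec = PhantomSpec(target_cvi=0.60, thickness_um=288.0, seed=1)
volume, boundaries, truth_masks = generate_phantom_volume(spec)
record = measure_eye(volume, boundaries, BinarisationParams())
print(round(record["cvi3d_whole"], 2), round(record["sfct_um"], 1))
```

prints `59.54 288.6`: the pipeline recovers the 60% ground truth to within
half a percentage point (the generator itself places lumina to within ±0.5
points of the target), and the SFCT of the 288-µm-thick phantom band is
288.6 µm after row quantisation. The same is available from a shell:

```sh
cvi3d simulate volume --out v.tif --meta v.json --boundaries b.csv --seed 1 --target-cvi 0.6
cvi3d measure --volume v.tif --meta v.json --boundaries b.csv --out record.json
```

The numbered drivers under `analysis/` run the full study narrative: example
phantoms (`01`), a 50-eye simulated cohort measured end to end (`02`,
mean 3D CVI 62.34 ± 1.35% at seed 1, |measured − true| ≤ 0.47 points),
agreement tables (`03`), and the recovery/calibration experiments (`04`).

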