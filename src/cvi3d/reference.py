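"""Published normative summary statistics for healthy adult eyes.

These are the overall mean (SD) values reported for a 50-eye, quintile-
stratified healthy cohort from a multi-ethnic Asian population-based study,
measured on 31-scan EDI-OCT macular volumes.  They serve two roles here:
as the default moments of the synthetic cohort generator, and as published
inputs to summary-level computations (coefficients of variation, the
difference-of-means identity behind Bland-Altman mean differences).
"""

#: Overall mean and SD of each CVI measure, in percent.
CVI_OVERALL = {
    "cvi3d_whole": (62.92, 1.57),
    "cvi3d_superior": (62.75, 1.93),
    "cvi3d_central": (63.35, 1.72),
    "cvi3d_inferior": (62.66, 1.70),
    "cvi2d_subfoveal": (63.53, 2.09),
}

#: Overall mean and SD of subfoveal choroidal thickness, in µm.
SFCT_OVERALL = (288.3, 85.6)

#: Per-quintile mean SFCT, µm — spans the thin-to-pachychoroid range the
#: stratified design was built to cover.
SFCT_QUINTILE_MEANS = (174.8, 239.5, 284.8, 331.3, 411.2)

#: Means for the fovea-centred 11/21/31-scan 3D CVI, derived from the
#: whole-macula mean and the published pairwise mean differences
#: (11 vs 31: 0.42; 21 vs 31: 0.19).
CVI_SUBSET_MEANS = {
    "cvi3d_11": (63.34, 1.65),
    "cvi3d_21": (63.11, 1.60),
    "cvi3d_31": (62.92, 1.57),
}

#: Covariate battery: (kind, parameters) per column.  Continuous entries are
#: (mean, sd) normal draws; "binary" entries are prevalence of the positive
#: level; "categorical" entries map level -> probability.
COVARIATES = {
    "age": ("normal", (53.8, 7.5)),
    "gender": ("categorical", {"Male": 0.5, "Female": 0.5}),
    "ethnicity": ("categorical", {"Chinese": 0.64, "Indian": 0.30, "Malay": 0.06}),
    "se": ("normal", (-0.7, 2.3)),
    "al": ("normal", (23.9, 1.1)),
    "iop": ("normal", (15.1, 3.4)),
    "mopp": ("normal", (52.3, 8.0)),
    "sbp": ("normal", (128.5, 19.2)),
    "dbp": ("normal", (76.0, 10.8)),
    "hba1c": ("normal", (5.9, 1.0)),
    "total_cholesterol": ("normal", (5.4, 0.8)),
    "hdl": ("normal", (1.2, 0.3)),
    "ldl": ("normal", (3.5, 0.8)),
    "bmi": ("normal", (24.0, 3.6)),
    "hypertension": ("binary", 0.34),
    "diabetes": ("binary", 0.08),
    "hyperlipidaemia": ("binary", 0.30),
    "cardiovascular_disease": ("binary", 0.04),
    "chronic_kidney_disease": ("binary", 0.02),
    "current_smoker": ("binary", 0.12),
}
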