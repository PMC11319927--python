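"""Published clinical benchmark statistics for the nine basal-bone indices.

Summary rows reported for a 1,000-patient clinical CBCT cohort (4,000 sagittal
sections, test split): per-index ground-truth and model-prediction mean ± SD
and the paired Wilcoxon p-values, for the pooled primary model and for the
sex-wise submodels and their routed ensemble.  The raw clinical images are not
public; these printed summaries are inputs for arithmetic and counting checks
(mean paired difference, significant-index counts), not reproduction targets.

Note: the published ensemble p-value row lists only eight entries for nine
indices (a defect of the printed table); it is kept as printed.
"""

from .geometry import INDEX_NAMES

#: pooled primary model on the overall test split
PRIMARY_EVAL = {
    "gt_mean": dict(zip(INDEX_NAMES, (17.58, 7.91, 21.82, 12.57, 9.69, 1.71, 7.98, 4.85, 4.85))),
    "gt_sd": dict(zip(INDEX_NAMES, (4.05, 3.81, 3.19, 3.31, 2.44, 1.28, 2.49, 1.22, 1.22))),
    "pred_mean": dict(zip(INDEX_NAMES, (17.79, 8.13, 21.95, 12.69, 9.83, 1.68, 8.15, 4.91, 4.92))),
    "pred_sd": dict(zip(INDEX_NAMES, (3.42, 3.15, 2.64, 2.75, 2.06, 1.07, 2.01, 1.03, 1.03))),
    "p": dict(zip(INDEX_NAMES, (0.028, 0.027, 0.122, 0.026, 0.022, 0.487, 0.009, 0.031, 0.021))),
}

#: sex-routed ensemble of the male- and female-only submodels, same test split
ENSEMBLE_EVAL = {
    "gt_mean": dict(zip(INDEX_NAMES, (17.58, 7.91, 21.82, 12.57, 9.69, 1.71, 7.98, 4.85, 4.85))),
    "pred_mean": dict(zip(INDEX_NAMES, (17.69, 8.03, 21.92, 12.65, 9.82, 1.69, 8.13, 4.91, 4.91))),
    "mae": dict(zip(INDEX_NAMES, (2.12, 2.04, 1.65, 1.73, 1.25, 0.63, 1.33, 0.62, 0.63))),
    # printed row: eight entries for nine indices, kept as published
    "p": (0.237, 0.205, 0.383, 0.114, 0.280, 0.043, 0.127, 0.131),
}
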