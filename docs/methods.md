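# Methods

`parityquant` implements a demographic-parity workflow for automatic
multi-quantification of the maxillary alveolar basal bone on 2D sagittal
CBCT sections: a shared-backbone multi-head CNN regressor for nine
morphometric indices, a subgroup bias audit, and a subdivide/retrain/pool
ensemble driven by the audited sensitive attribute. Because clinical CBCT
data of this kind are not publicly distributable, the package ships a
synthetic sagittal-section generator with analytically exact ground truth;
every stage of the pipeline is specified, tested and calibrated on that
generator.

## Geometry model and index operators

A sagittal section is a set of landmarks and polylines in continuous mm
coordinates (y increasing apically): alveolar crest point, root apex, tooth
axis and bone axis (directed lines), basal-bone boundary, and buccal/palatal
cortical contours. The nine indices are:

* lengths — `LTAcb`, `LTAab` (crest/apex to the basal boundary along the
  tooth axis) and `LBAcb`, `LBAab` (the same along the bone axis);
* widths — `apical2mm` (bucco-palatal width 2 mm apical to the apex),
  `WTAB`/`WTAP` (buccal/palatal contour to the tooth axis) and
  `WBAB`/`WBAP` (the same to the bone axis).

All operators reduce to line–polyline intersections solved segment-by-segment
as 2×2 linear systems (half-open segment intervals so shared vertices count
once; crossings closer than 1e−9 are merged). Conventions that the source
description leaves open are configurable and default to:

* axis widths measured at the axis/basal-boundary intersection level,
  perpendicular to the respective axis (`width_level_offset_mm = 0`);
* "2 mm apical" = 2 mm beyond the apex along the tooth axis, away from the
  crown;
* when a perpendicular crosses a contour more than once, the crossing nearest
  the axis is used.

The operators are rigid-motion invariant to 1e−9 mm and scale-equivariant
(provided fixed offsets such as the 2 mm apical level are scaled along);
both properties are asserted in the test suite, together with agreement with
an independent polyline-intersection oracle (shapely) on irregular fixtures.

## Synthetic population and study conditions

The generator emulates the study population the workflow targets: 1,000
patients by default, sex ratio 388:612 (male fraction 0.388), age
36.15 ± 13.09 y truncated at 18, four tooth sites (#11, #12, #21, #22) per
patient, and a patient-wise 6:2:2 train/validation/test split
(largest-remainder apportionment, remainder ties resolved in split order).

Morphology is parametric per tooth (buccal/palatal half-widths, crest-apex
and crest-basal distances, basal slope, tooth tilt, contour taper), with
means chosen so the generated index distributions bracket published clinical
ranges (LTAcb ≈ 17.6 mm, apical2mm ≈ 9.7 mm, WTAB ≈ 1.7 mm, WBAB ≈ 4.9 mm).
`sex_effect` multiplies the width-governing parameters for males
(default 1.0 = no dimorphism; the biased study scenario uses 1.3, matching
the direction reported for basal-bone width dimorphism). Age and tooth site
carry no morphological effect, so the expected audit verdict on synthetic
data is unambiguous. Tooth sites are drawn independently
(`patient_correlation = 0`, configurable); correlated sites would make the
four images of a patient pseudo-replicates and were found to inflate
cluster-sampling false positives in the stratum tests.

Images are rasterised from the geometry polygons at pixel centres
(background < bone < tooth intensity), Gaussian-blurred and noised. Ground
truth is always measured on the exact geometry; the *rendered* geometry is
deliberately perturbed to emulate the irreducible mismatch between what an
image shows and what a reference annotation measures:

* bucco-palatal jitter of each cortical contour and of the tooth
  (`render_jitter_mm = 0.4` per structure) and apico-coronal jitter of the
  basal boundary (`basal_jitter_mm = 0.25`; the axis widths are taken at the
  basal level, so this contributes to width ambiguity as well);
* a sex-conditional imaging relationship: male cortical boundaries render
  shifted toward the axis by `render_sex_offset_scale × (sex_effect − 1)` mm
  per side (default scale 3, i.e. 0.9 mm at effect 1.3; exactly zero in the
  null scenario). This models subgroup-specific cortical appearance and is
  the mechanism by which a pooled model trained on a female-majority dataset
  systematically mis-measures male widths unless it can infer sex from an
  ambiguous image — the phenomenon the demographic-parity strategy corrects.

What the generator does *not* emulate: 3D geometry, beam hardening, scatter,
metal artifacts, pathology, real annotation protocols. Passing tests on this
generator demonstrate that the pipeline recovers a known injected bias
structure; they do not certify performance on clinical images.

## Regressor

`MultiQuantRegressor` is a scikit-learn-style estimator around a numpy
implementation of residual CNNs (im2col convolution with explicit backward
passes, verified against finite differences). One trunk yields a pooled
feature vector; nine heads (Linear–ReLU–Linear) own their parameters, so
head gradients never touch other heads while trunk parameters are shared.
Backbones: a two-stage `small-resnet` (stride-2 stem, 8/16/32 channels) for
CPU-scale work, plus the six standard residual recipes
(ResNet-50/101, ResNeXt-50 32×4d / 101 32×8d, Wide-ResNet-50/101-2 —
simplified stem, no batch norm) for fidelity configurations.

Training choices:

* labels z-scored per index on the training split (indices span
  1.7–22 mm; unnormalised MSE would be dominated by the long lengths); loss
  is the unweighted mean of the nine per-index MSEs; predictions are
  de-normalised to mm;
* Adam (the source names no optimizer); defaults lr 5e−4, batch 4,
  200 epochs mirror the reported selected hyperparameters; the desk-scale
  configuration uses lr 2e−3, batch 32, 30 epochs at 64 px / 0.5 mm px⁻¹;
* horizontal-flip augmentation flips the image only — all nine labels are
  invariant under bucco-palatal mirroring (widths unsigned, lengths
  axis-wise);
* Polyak tail averaging: final weights are the mean of end-of-epoch weights
  over the last quarter of training (`avg_tail_frac = 0.25`), damping
  optimization noise;
* training-split mean-bias calibration: after fitting, the per-index mean
  residual on the training split is subtracted from all predictions. This
  removes seed-idiosyncratic global offsets (which would otherwise register
  as significant "bias" in every stratum of every attribute) without
  touching test data and without affecting genuinely subgroup-conditional
  bias, whose pooled mean is already ≈ 0.
* `pretrained` weights are supported as an explicit checkpoint path; nothing
  is downloaded.

`select_model` trains a candidate list and keeps the minimum validation MSE
(mm², averaged over heads), ties resolved in candidate order. Grad-CAM for a
regression head uses the spatially averaged gradient of the head's scalar
output w.r.t. the final convolutional feature map as channel weights;
the rectified weighted sum is upsampled to the input size and min–max
normalised (an all-zero map stays zero).

## Statistics

* Paired Wilcoxon signed-rank on pred − gt: zeros dropped, mid-ranks for
  ties, exact two-sided p by generating-function convolution over the 2ⁿ
  sign assignments for effective n ≤ 25 (doubled ranks keep sums integral),
  tie- and continuity-corrected normal approximation beyond; all-zero
  differences give p = 1.
* Agreement: mean difference (pred − gt, stated explicitly since published
  tables are inconsistent about the sign), SD of differences, MAE, MSE,
  Pearson r, and ICC(2,1) — two-way random effects, absolute agreement,
  single measures — computed from the two-way ANOVA mean squares. Zero
  variance yields NaN markers, not exceptions. Bland–Altman limits are
  bias ± 1.96 SD.
* No multiple-testing correction is applied across the nine indices or
  strata, matching the per-test α = 0.05 convention of the clinical
  workflow this mirrors; with 27 stratum tests per attribute set, stray
  5%-level hits are expected and the audit is designed around counts, not
  single tests. A deliberate, questionable convention.

## Subgroup audit and parity ensemble

For each attribute (sex, age group, tooth site), level and index, the audit
runs the paired Wilcoxon within the stratum; strata with fewer than 5 pairs
are excluded as underpowered. An attribute's disparity is max − min of the
per-level significant-index counts; the sensitive attribute is the argmax
(ties: larger total count, then attribute order), and a disparity threshold
(default 1) decides whether anything is flagged at all.

Subdivision restricts the *original* patient-wise split to each level of the
sensitive attribute (a fresh per-level 6:2:2 re-split is available as an
option), so the union of level test sets is exactly the pooled test set and
before/after comparisons share their test records. Submodels inherit the
primary model's architecture and hyperparameters, with per-level seeds
derived from the global seed and level name. The ensemble is a routing pool:
each test record is scored by its own level's submodel; pooled MAE and mean
difference are therefore exactly the record-count-weighted combinations of
the per-level values (asserted as identities). Routing requires the
attribute as input metadata; inferring sex from the image is out of scope.

Two before/after summaries are reported: the pooled-table significant count
(the published-table analogue) and the per-stratum significant count summed
over the subdivision attribute's levels. The latter is the quantity the
parity strategy targets — after mean calibration, opposite-signed per-sex
biases largely cancel in the pooled table but remain fully visible
per stratum.

## Desk-scale study conditions and what the Monte-Carlo shows

The fairness Monte-Carlo (10 replicates per scenario; per-replicate seeds
derived via `SeedSequence` from the base seed) uses 200 patients, 64 px
images at 0.5 mm px⁻¹, the `small-resnet` backbone and 30-epoch training —
about half a minute per replicate on one CPU core. Under the biased scenario
(`sex_effect = 1.3`, male fraction 0.388) the routed ensemble reduces (or at
least does not increase) the per-stratum significant-bias count in 8–9 of 10
replicates; the audit's sensitive-attribute verdict lands on sex in roughly
two-thirds of replicates (see the limitations below on the power of the
count-disparity rule at this scale). Under the null (`sex_effect = 1.0`) no
attribute carries systematic disparity, but chance disparities of ≥ 2 still
appear in a substantial fraction of replicates — with two-sided α = 0.05
tests over 9 indices and 9 strata, the probability of a max disparity ≥ 2 is
≈ 0.43 per replicate even for perfectly independent uniform null p-values
(the binomial floor), and positive cross-index residual correlation raises
it. These are statements about the designed synthetic scenario, at this
problem size, not about clinical data.

## Numerical and degenerate-case choices

* Geometry validation tolerances: apex on the tooth axis within 1e−6 mm;
  the basal boundary must cross each axis exactly once.
* Invalid random geometries are re-drawn (bounded retries); field-of-view
  overflows during rendering trigger a redraw of the tooth.
* Annotation CSV round-trips exactly (full-precision float repr, pixel
  coordinates with mm conversion via `pixel_spacing`, 0-based pixel centres).
* `WBAB` and `WBAP` are computed as two independent measurements even though
  published summaries print identical values for them.
* Wilcoxon exact/approximate switch at n = 25; the approximation was checked
  against the exact path and scipy in the tests.
* Empty validation splits are permitted for submodels (validation history is
  simply absent); empty levels are skipped by the pooling stage.

## Known limitations

* The numpy networks are CPU-oriented; the six fidelity backbones build and
  run forward/backward but are impractical to train at clinical scale here.
* The audit's disparity score conflates bias differences with power
  differences when strata differ in size; the calibration and averaging
  steps above mitigate but do not eliminate this. Two structural effects
  limit its power at the 200-patient scale: after mean calibration the two
  sex strata satisfy n-weighted bias cancellation, which pins the ratio of
  their test statistics near 0.8 so their significant counts tend to cross
  the α threshold together (capping the max − min disparity); and the
  3- and 4-level attributes accumulate chance disparities of 1–3 that can
  tie or beat a genuine sex disparity, with the tie-break (larger total
  count) favouring multi-level attributes. In practice the verdict lands on
  sex in roughly two-thirds of biased-scenario replicates.
* Wilcoxon treats the four images of a patient as independent pairs,
  mirroring the clinical analysis it reproduces; with correlated sites this
  is pseudo-replication.
* The sensitive-attribute rule is deterministic but heuristic; it is not a
  formal fairness criterion (no equalized odds, no calibration-by-group).
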