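# parityquant

Demographic-parity multi-quantification of the maxillary alveolar basal
bone from 2D sagittal CBCT sections.

Surgeons planning anterior maxillary implants need nine morphometric
indices per tooth section — four lengths along the tooth axis (TA) and bone
axis (BA) to the basal-bone boundary (`LTAcb`, `LTAab`, `LBAcb`, `LBAab`)
and five bucco-palatal widths (`apical2mm`, `WTAB`, `WTAP`, `WBAB`,
`WBAP`). A single CNN with one feature-extraction backbone and nine
parallel regression heads can predict all of them at once, but bone
morphology is sexually dimorphic and clinical datasets are demographically
skewed, so a pooled model can systematically mis-measure a minority
subgroup. This package implements the full workflow for detecting and
correcting that failure:

1. **Multi-quantification model** — `MultiQuantRegressor`, a scikit-learn
   style estimator over a residual CNN (numpy, CPU) with nine independent
   scalar heads over fully shared trunk features; loss is the mean of the
   per-index MSEs on z-scored labels, with Grad-CAM explanations per head.
2. **Subgroup audit** — for each demographic attribute (sex, age group,
   tooth site), each level, and each index, a paired Wilcoxon signed-rank
   test between predictions and ground truth; the attribute with the
   largest max−min spread of significant-index counts across its levels is
   the *sensitive attribute*.
3. **Demographic-parity ensemble** — the dataset is subdivided by the
   sensitive attribute, one submodel is trained per level with unchanged
   hyperparameters, and each test record is scored by its own level's
   submodel (a routing pool, not an average). Agreement is summarised by
   mean difference, MAE, Pearson r, ICC(2,1) and Bland–Altman limits.

Because clinical CBCT sections cannot be redistributed, the package includes
a synthetic sagittal-section generator (`parityquant.synthetic`) producing
demographically structured patients, parametric tooth/bone geometries with
*analytically exact* ground truth, and rendered grayscale images — including
a configurable sex effect on bone widths and a sex-conditional imaging
relationship, so the whole audit-and-repair loop is testable end to end.
See `docs/methods.md` for the model, the statistics, and the design of the
synthetic study conditions.

## Worked example

```python
from parityquant import PipelineConfig, run_full

config = PipelineConfig.desk_scale(seed=2, sex_effect=1.3, male_fraction=0.388)
bundle = run_full(config)

report = bundle["audit_report"]
print("sensitive attribute:", report.sensitive_attribute)
print("disparity:", report.disparity)
print("per-sex significant-index counts:", report.significant_counts["sex"])
print("bias count, pooled model:", bundle["bias_count_primary"])
print("bias count, parity ensemble:", bundle["bias_count_ensemble"])
```

Output (seed 2):

```
sensitive attribute: sex
disparity: {'sex': 4, 'age_group': 1, 'tooth_site': 0}
per-sex significant-index counts: {'female': 7, 'male': 3}
bias count, pooled model: 10
bias count, parity ensemble: 2
```

Read: in a 200-patient synthetic cohort with female-skewed demographics and
30 % wider male bones, the pooled model's predictions are significantly
biased in 7 of 9 indices for females and 3 for males, so the audit flags
sex (disparity 4 versus ≤ 1 for age and tooth site). After subdividing by
sex, retraining one submodel per sex, and pooling the routed predictions,
the summed per-sex significant-bias count falls from 10 to 2.

The same workflow is available from a shell:

```bash
parityquant all --seed 2 --outdir out/   # generate → train → audit → parity → report
```

which writes the manifest, evaluation tables (CSV), the audit report
(JSON), Bland–Altman data, Grad-CAM maps (PNG) and a Markdown summary.

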