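# kbxfer

Knowledge-based DVH prediction and inter-consortium transferability
validation for right whole-breast tangential-field radiotherapy.

## The problem

Knowledge-based (KB) treatment planning predicts the dose–volume histogram
(DVH) a new patient can achieve from a library of prior clinical plans.
Before a KB model trained at one institution — or by one national
consortium — can be used elsewhere, its *transferability* has to be
audited: does it still predict accurately for patients whose anatomy and
contouring practice differ from its training distribution?

`kbxfer` is an open, tested implementation of that audit for the
whole-breast tangential-field setting (prescription 40 Gy in 15
fractions).  It is aimed at medical-physics researchers who want a
reproducible, vendor-independent reference for the full chain:

1. **DVH engine** — cumulative DVHs `V(d)` (fraction of organ volume
   receiving ≥ d Gy) from dose grids and structure masks, plus the scalar
   metrics V*x*Gy / V*x*% / D*x*% and mean dose.
2. **Geometry features** — organ volumes, PTV–organ overlap, and the
   signed distance-to-target histogram (DTH); a PCA over these features
   yields per-patient scores whose first component, PC1, flags patients
   outside a model's training envelope.
3. **KB predictor** — `KBPlanModel` / `KBPlanResults`
   (statsmodels-style): PCA of the training DVHs, ordinary least squares
   from geometry PC scores to DVH PC scores, and prediction bands
   `mean ∓ k·Σ_c σ_c·|w_c|` built by shifting each predicted score by
   ±k residual standard deviations (default k = 1.28 ≈ an 80% two-sided
   normal interval).
4. **Transfer validation** — for each patient i and model j the midpoint
   prediction DVH_ij = (lower+upper)/2, the per-patient model average
   DVH̄_i = (1/10)·Σ_j DVH_ij with pointwise sample SD σ_i (denominator
   n−1), and their cohort averages DVH_int = (1/20)·Σ_i DVH̄_i and
   SD_int = (1/20)·Σ_i σ_i; Δ = clinical − predicted accuracy metrics
   with ±2 Gy (mean dose) and ±5-point (V20Gy) bands and Wilson 95% CIs;
   the four-way optimal/suboptimal/improved/failed band categorization;
   the PC1 10th–90th-percentile criterion; Mann–Whitney U, Welch t and
   exact Wilcoxon signed-rank cohort comparisons.
5. **Synthetic two-consortium generator** — ten source-consortium
   institution styles (one with zero PTV–lung overlap) and an external
   consortium with systematically different anatomy, so the whole pipeline
   is testable end to end without clinical data.

## Worked example

```python
from kbxfer import RunConfig, run_experiment

result = run_experiment(RunConfig(seed=1))
print(result.summary())
```

prints (abridged):

```
Two-consortium KB transferability experiment
============================================================
seed: 1   institutions: 10   test patients per arm: 20

--- intra-consortium ---
records (patient x model): 200
categories: optimal: 120 (60.0%), suboptimal: 15 (7.5%), improved: 56 (28.0%), failed: 9 (4.5%)
delta_mean_dose_within_2gy: 97.9%  (95% CI 94.7-99.2%)
lung mean dose (model-averaged): 4.94 +/- 0.55 Gy

--- inter-consortium ---
records (patient x model): 200
delta_mean_dose_within_2gy: 83.9%  (95% CI 78.2-88.4%)
lung mean dose (model-averaged): 4.65 +/- 0.83 Gy
PC1 outside fraction by model: ..., institution_6: 0.80, ...

PC1-outside fractions, Wilcoxon signed-rank: W=1.0, p=0.0076
```

Reading the numbers: within the source consortium the ten institution
models agree closely (inter-model SD 0.55 Gy on the predicted lung mean
dose) and almost every prediction is within 2 Gy of the clinical plan.
On the external cohort the inter-model spread grows (0.83 Gy), the
accuracy-band proportion drops, and the zero-overlap institution
(`institution_6`) has by far the largest fraction of patients whose lung
PC1 falls outside its training 10th–90th percentile window — the
signature of a model applied beyond its training geometry.  The Wilcoxon
test confirms that PC1-outside fractions are systematically higher on the
external cohort.

A single fitted model reads like any statsmodels result:

```python
from kbxfer import KBPlanModel

res = KBPlanModel(geometry_summaries, lung_dvhs, organ="IPSI_LUNG").fit()
print(res.summary())            # components, residual SDs, PC1 percentiles
band = res.predict_band(new_patient_geometry)
```

There is also a CLI (`kbxfer simulate/train/predict/validate/run`); try
`kbxfer run --seed 1 --out out/ --plots`.

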