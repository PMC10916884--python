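# foveaspec

Quantitative analysis of foveal structure from OCT for predicting visual
acuity in foveal hypoplasia (e.g. albinism).

## The problem

Foveal development involves three anatomical specializations relative to the
surrounding parafovea: lateral displacement of the inner retinal layers
(forming the pit), elongation of cone outer segments, and thickening of the
outer nuclear layer. In foveal hypoplasia these specializations are variably
arrested, and their severity is usually scored on the ordinal Leicester
scale (1a, 1b, 2, 3, 4). Categorical grades correlate with best-corrected
visual acuity (BCVA) but hide a wide continuum of structure within each
grade.

`foveaspec` implements a continuous alternative: three parafovea-normalized
specialization ratios measured from segmented OCT B-scans,

- **IRL ratio** = mean inner-retinal-layer thickness (ILM→INL/OPL) at
  ±1 mm ÷ foveal IRL thickness,
- **OS ratio** = maximum outer-segment length (EZ→IZ peak distance from
  longitudinal reflectivity profiles, Gaussian-fit over 21 samples) ÷ mean
  OS length at ±1.75 mm,
- **ONL ratio** = foveal outer-nuclear-layer thickness (HFL-outer→ELM) ÷
  mean ONL thickness at ±1.75 mm,

each equal to 1 for a flat (fully hypoplastic) retina and rising with
specialization. BCVA (logMAR) is then predicted with the combined linear
model

```
logMAR_pred = 1.128 − 0.076·ONL + 0.396·Age18 + 0.131·IRL − 0.449·OS
              − 0.579·Age18·IRL + 0.206·Age18·OS
```

where `Age18` is 1 for adults (age ≥ 19 years) and 0 otherwise. The package
covers the full chain: scan-geometry preprocessing, LRP peak analysis, layer
thickness profiles, rule-based grading with ROC-calibrated cutoffs,
model fitting with leave-one-out cross-validation and stepwise term
selection, and agreement statistics (linearly weighted Cohen's kappa,
Bland–Altman with bias-trend regression). A parametric synthetic-data module
generates foveal geometries, rendered B-scans, and cohorts with closed-form
ground truth, so every stage is testable without patient data.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```
python analysis/01_simulate_cohort.py   # cohort table with known truth
python analysis/02_measure_eyes.py      # render B-scans, re-measure ratios
python analysis/03_grade_and_roc.py     # ROC-calibrate grading cutoffs
python analysis/04_fit_models.py        # categorical vs combined models
python analysis/05_agreement.py         # kappa + Bland–Altman
```

`02_measure_eyes.py` prints (seed 1):

```
measured 74 of 74 eyes (render noise 0.01, band blur 4.0 µm)
  irl_ratio : max rel err 1.43%, median 0.767%
  os_ratio  : max rel err 1.14%, median 0.561%
  onl_ratio : max rel err 0.00%, median 0.000%
```

i.e. ratios measured from rendered, noisy B-scans stay within ~1.5% of the
generating geometry's analytic truth. `04_fit_models.py` then prints:

```
model                  adj R2 (CV)  RMSE (CV)  R (CV)
categorical_grade           -0.081      0.306   0.097
combined_fixed_terms         0.494      0.205   0.734
```

the leave-one-out goodness of fit of each acuity model on this cohort: the
combined quantitative model explains about half of the acuity variance
(cross-validated adjusted R² ≈ 0.5 at the calibrated noise level) while the
categorical grade, a coarsening of the same information, predicts far worse.

The same stages are available as a CLI (`foveaspec simulate|preprocess|
osmetrics|layermetrics|grade|fit|agree|analyze`) for running on external
images, segmentation CSVs, and cohort tables.

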