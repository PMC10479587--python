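# glompath

Explainable classification of three glomerular diseases — minimal change
disease (MCD), membranous nephropathy (MN) and thin-basement-membrane
nephropathy (TBMN) — from PAS-stained glomerulus ROI images, via a
biomarker-feature-extraction (BFE) pipeline rather than a black-box CNN.

The pipeline is aimed at renal-pathology image analysis: each glomerulus
ROI (image + Bowman-capsule boundary mask) is color-normalized, segmented
into three sub-glomerular structures (luminal space, glomerular tuft =
GBM + mesangial matrix, nuclei) with a Gaussian Naive Bayes color model,
and summarized by a panel of **233 explainable biomarkers** — first-order
color statistics, morphology (containment ratios, shape, interstructural
distances, Euclidean-distance-transform thickness maps) and microstructural
texture (masked GLCM, color-vector rotation-invariant LBP, wavelet subband
energies). Gini importance from a random forest ranks the panel, the top
k = 10 features feed a linear discriminant (LDA) classifier, and a
patient-level diagnosis averages the probability triplets of the patient's
four most confident glomeruli:

```
label(glom)   = argmax_c  P_LDA(c | top-10 biomarkers)
P(patient)    = mean of P over the 4 glomeruli with highest max-probability
label(patient)= argmax_c P(patient),  confidence = max_c P(patient)
```

Validation is patient-grouped throughout: a stratified 67/33 patient-level
holdout and stratified-grouped 5-fold cross-validation, so no patient's
glomeruli ever straddle a split.

Because clinical datasets of this kind are private, the package ships a
**phantom generator**: synthetic PAS-like glomeruli with known structure
masks whose disease presets differ chiefly in tuft-band thickness
(MN thick > MCD > TBMN thin), with patient-level stain and morphometry
variability. Every stage is validated end to end against this known ground
truth.

## Worked example

```python
from glompath.pipeline import RunConfig, run_bfe

result = run_bfe(RunConfig(out_dir="demo_run"))
print(result.cv["mean_accuracy"], result.dice)
print(result.glomerular_metrics["accuracy"], result.patient_metrics["accuracy"])
```

This generates the default 45-patient phantom cohort (15 per disease,
6–10 glomeruli each, 384 px canvas), runs the full pipeline, and logs:

```
[glompath] stage phantom: 367 glomeruli
[glompath] stage outliers: excluded 0
[glompath] stage segment: mean Dice {'luminal': 0.997, 'tuft': 0.952, 'nuclei': 0.981}
[glompath] stage features: 367 x 233
[glompath] stage cv: 100.0 +/- 0.0%
[glompath] stage evaluate: glomerular acc 100.0%, patient acc 100.0%
```

Read: sub-glomerular segmentation recovers the ground-truth structure maps
at Dice ≥ 0.95 per class; the grouped 5-fold CV and the 15 held-out
patients are classified perfectly — expected, since the phantom disease
contrasts (tuft thickness) are planted far above the noise floor.  Under
label permutation the same protocol falls to chance (≈ 33%), confirming the
accuracy comes from the planted signal, not leakage.  Artifacts
(`features.csv`, `model.json`, `predictions.csv`, `patient_report.csv`,
`metrics.json`) land in `demo_run/`.

The same run is available from the shell:

```bash
glompath phantom --n-per-disease 15 --image-size 384 --seed 0 --out-dir cohort/
glompath run --manifest cohort/manifest.csv --out-dir demo_run
glompath verify-tables
```

`glompath verify-tables` recomputes the published reference metrics
(accuracy, macro precision/recall, F1, per-class recalls) from the embedded
glomerular- and patient-level confusion matrices and reports pass/fail per
value.

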