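# Methods

This note documents the models, conventions and design choices behind
`glompath`, in the order the pipeline runs them.

## Problem setting

Three glomerular diseases are distinguished on PAS-stained glomerulus ROIs
mainly by the state of the capillary wall: membranous nephropathy (MN)
thickens the glomerular basement membrane, thin-basement-membrane
nephropathy (TBMN) thins it, and minimal change disease (MCD) looks close
to normal at light-microscopy resolution. The pipeline makes that
morphology explicit: it segments each glomerulus into luminal space,
glomerular tuft (GBM + mesangial matrix, treated as one class) and nuclei,
measures an interpretable biomarker panel per structure, and classifies
glomeruli and then patients.

## Phantom generator

Real cohorts of this kind are private, so the package generates synthetic
glomeruli with known ground truth. Geometry: the Bowman capsule is an
ellipse (random axes and orientation); the tuft is an annular band around a
lobulated mid-contour (low-frequency Fourier perturbation) whose local
full-width is drawn from N(thickness mean, sd) and smoothed along the
contour; nuclei are random ellipses scattered over tuft and luminal
regions. Colors are Gaussian per structure (pale pink luminal, magenta
tuft, dark blue-purple nuclei — a PAS-like palette, identical across
diseases so class signal is geometric, not a color shortcut), lightly
blurred (sigma 0.6 px).

Disease presets (full band width on the nominal 1500 px canvas): MN 60 ± 8,
MCD 36 ± 6, TBMN 16 ± 3 px; nuclei counts 35–75 and radii 13–26 px by
disease. These are plausible placeholders expressing the qualitative
ordering MN > MCD > TBMN, not calibrated morphometry — no public
quantitative reference exists for these classes. Each *patient* perturbs
the preset (thickness scale ~ N(1, 0.10), additive stain shift
sd 7 intensity levels shared by the patient's glomeruli), emulating
biopsy-to-biopsy and slide-to-slide variability; without it every
within-disease glomerulus is statistically identical and any single feature
separates the classes, which makes feature-selection behavior
uninformative.

Profiles are parameterized by canvas size and scale linearly. The default
cohort runs on a 384 px canvas: at that scale the thinnest structure (TBMN
band, ≈ 4 px) still spans several pixels, which a distance-transform
thickness measurement needs; smaller canvases quantize the EDT to one or
two levels. Single-phantom unit tests use 256–512 px as convenient.

What the phantoms do *not* model: capillary-loop topology inside the tuft,
chromatin texture, staining gradients, scanner artifacts, out-of-focus
regions, crescents or sclerosis. Passing tests therefore demonstrate that
the pipeline recovers planted contrasts of the kind the diseases exhibit —
not clinical performance on real slides.

## Preprocessing

* **Size outliers.** ROIs whose boundary-mask area falls below the Tukey
  lower fence (Q1 − 1.5·IQR, factor configurable) are excluded; only the
  small side is fenced, since undersized "glomeruli" are typically
  fragments or mis-crops. Fewer than four ROIs → no exclusion.
* **Color normalization.** Reinhard-style moment matching in CIELAB:
  per channel, x' = (x − μ_src)·(σ_tgt/σ_src) + μ_tgt, with source
  statistics computed over tissue (inside the boundary mask) only so
  background white does not dilute them; a numerically constant channel
  (σ < 1e-6) maps to the target mean. The normalization target defaults to
  the masked Lab statistics of the cohort's first ROI (by glomerulus id)
  and is stored as 6-number JSON.
* **Re-center / crop / resize.** The uniform crop side is the largest
  bounding-box side over the cohort; each ROI is cropped to a half-open
  side×side window centered on its mask centroid (rounded half-up), padded
  with the median out-of-mask color where needed, then resized with bicubic
  interpolation. Pixel coordinates are 0-based.

## Sub-glomerular segmentation

A Gaussian Naive Bayes color model over RGB: per class and channel,
population mean and variance (floored at 1e-4 of the squared channel
range), priors defaulting to empirical frequencies. Pixels inside the
boundary mask get the class maximizing the joint log posterior; one pass of
3×3 majority-vote smoothing (votes counted over in-mask neighbors only)
suppresses salt-and-pepper noise. Ties break to the earlier class in the
fixed order luminal < tuft < nuclei. The smoothing can flip pixels at
sharp ground-truth corners (five opposing neighbors outvote four own), so
exact-recovery tests disable it; in practice it raises Dice on noisy
phantoms. Training pixels come from annotated structure maps of the
*training* patients only, sampled class-balanced and seeded.

## The 233-biomarker panel

An ordered, versioned registry (96 color + 47 morphological + 90 texture):

* **Color (96).** mean, variance (population), skewness, excess kurtosis,
  histogram energy Σp² and histogram entropy −Σp·log₂p (256 bins) of
  R, G, B and hue (scaled to [0, 255]), within each structure and the whole
  glomerulus. Moments of constant regions use the 0/0 → 0 convention.
* **Morphological (47).** Eight containment area ratios; per-structure
  equivalent diameter √(4A/π) and circularity 4πA/P² (Crofton perimeter —
  unbiased for smooth shapes, a disc scores ≈ 1.0) plus solidity for
  luminal and tuft; mean and max Euclidean distance from each of six
  ordered structure pairs; intrastructural thickness = max, median and
  total of each structure's Euclidean distance transform (the per-pixel
  half-thickness maps); ten whole-glomerulus shape/size descriptors.
* **Texture (90).** Masked GLCM (32 gray levels, distance 1, four angles
  pooled, both pixels of a pair inside the structure; symmetric and
  normalized) → contrast, correlation, energy, homogeneity, entropy for the
  three structures and the whole glomerulus (20). Color-vector LBP:
  rotation-invariant uniform codes (P = 8, R = 1) per RGB channel,
  10-bin normalized histograms restricted to the structure, for tuft and
  whole-glomerulus scopes (60); equal neighbors count as ≥ center, so flat
  texture concentrates in the all-ones bin. Two-level db4 wavelet
  decomposition of the masked bounding-box crop (periodization mode —
  exact Parseval energy conservation): all seven subband energies plus the
  LL2/LH2/HL2 entropies (10 of the 14 raw values; the raw extractor
  returns all 14).

Empty structures yield zeros everywhere (documented degenerate
conventions) so the classifier never sees non-finite inputs; `extract_all`
asserts finiteness. Entropies are base 2 throughout. The exact membership
of the panel is a registry artifact: downstream code depends only on the
count (233), order stability and per-extractor correctness, and the
registry is exported as JSON for provenance.

## Selection, classification, aggregation

Gini importance = normalized mean decrease in impurity from a
500-tree random forest (√p features per split, fixed seed); ranking ties
break by registry order (stable sort). The top k = 10 features feed an LDA
classifier; the least-squares pooled-covariance solver is used because it
degrades gracefully when the pooled covariance is singular (few samples,
correlated biomarkers). Patient-grouped validation uses
stratified-grouped k-fold (folds partition patients and balance diseases;
ranking and selection are re-fit inside each training fold) and a
stratified 67/33 patient-level holdout (per disease, round(n/3) patients to
test). A patient's diagnosis averages the probability triplets of their
top-4 glomeruli ranked by maximum class probability (ties by glomerulus
id); patients with fewer than four use all.

## Metrics

Confusion matrices are rows = predicted, columns = true, class order
(MCD, MN, TBMN). Accuracy = 100·trace/total. Precision/recall are
macro-averaged; F1 is the harmonic mean of macro precision and macro
recall *after* rounding each to two decimals — the convention under which
the embedded reference tables reproduce exactly (71.90/71.59/70.43/71.01
glomerular; 73.33/70.79/71.67/71.23 patient). Per-class table percentages
round to integers. `verify_tables` recomputes all fourteen values from the
embedded matrices.

## Determinism and problem sizes

Every stochastic stage has its own seed (phantom, split, forest, pixel
sampling); identical configs produce byte-identical `metrics.json`
(the embedded config omits the output path). The default cohort —
45 patients, 6–10 glomeruli each, 384 px — runs the full pipeline in about
4–5 minutes on one CPU; the deterministic small-cohort tests use 96–128 px
canvases.

## Known limitations

* Phantom realism as listed above; perfect phantom-cohort accuracy is a
  property of the planted effect sizes, not a clinical claim.
* The Naive Bayes "modification" is realized as modal smoothing, and the
  masked-statistics variant of Reinhard normalization is one reasonable
  reading; other variants exist.
* With many highly correlated discriminative biomarkers, impurity-based
  importances spread thin (redundancy masking); the planted-discriminator
  recovery check asks only that a tuft-thickness feature reaches the
  top 10, not that it ranks first.
* Gaussian-scale-space and Gabor texture families are out of scope.
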