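# mitotexture

Texture-based quantification and classification of mitochondrial morphology
in 2D confocal fluorescence microscopy.

Mitochondria continuously remodel between interconnected tubular networks
(**fibers**), short unbranched fragments (**rods**) and small disconnected
spots (**puncta**); the balance between these states tracks metabolic and
inflammatory cell states. Skeleton-based network tools struggle exactly where
this matters most — heavily fragmented or ambiguous structures. This package
instead treats each small region of interest (ROI) as a *texture*: it
computes a 93-descriptor suite of first-order and gray-level matrix features,
selects the most discriminative ones by recursive feature elimination, and
classifies morphologies (and treatment conditions) with a decision tree and a
one-vs-rest SVM.

## What it computes

For each ROI (the reference layout uses 69×69 px at 0.035 µm/px), after an
optional pre-processing chain (1% percentile saturation rescale → CLAHE →
3×3 adaptive Wiener filter → σ = 0.5 px Gaussian), intensities are
discretized to gray levels *i* = 1…N<sub>g</sub> (fixed bin width 25 by
default) and six feature families are extracted, 93 features in total:

| family | count | built from |
|---|---|---|
| first-order | 18 | the intensity histogram (mean, percentiles, skewness, non-excess kurtosis, energy, entropy, …) |
| GLCM | 24 | co-occurrence matrix P(i,j) at distance 1 over 4 angles, symmetrized and angle-averaged (contrast, correlation, IMC1/2, MCC, inverse differences, …) |
| GLRLM | 16 | run-length matrix over 4 directions (short/long-run emphases, run-length non-uniformity, …) |
| GLSZM | 16 | 8-connected size-zone matrix (zone percentage, size-zone non-uniformity, area emphases, …) |
| NGTDM | 5 | neighborhood gray-tone differences (coarseness, busyness, complexity, contrast, strength) |
| GLDM | 14 | dependence matrix with tolerance α = 0, dependence size j = 1 + dependent 8-neighbors |

Typical texture signatures: puncta ROIs are dominated by homogeneous
background, giving high long-run emphasis, high kurtosis/skewness and low
GLCM contrast; fiber networks produce dense intensity transitions, giving
high short-run emphasis and contrast; rods sit between the two and overlap
most with fibers.

Downstream, the package provides z-scored recursive feature elimination
(linear-SVM coefficient ranking, top 20 kept by default), decision-tree and
one-vs-rest SVM classifiers (linear or RBF kernel), repeated stratified
k-fold cross-validation with selection refit inside every training fold,
bootstrap ROC/AUC confidence intervals, and a per-feature two-group
statistics pipeline (MAD outlier replacement with k = 2.1, Shapiro–Wilk
screening, Welch's t or Mann–Whitney U).

A synthetic ROI generator (`mitotexture.synthgen`) draws the three
morphologies with controlled noise (Poisson shot + Gaussian read noise) so
the whole pipeline is testable without microscope data.

## Worked example

Simulate a benchmark of 30 ROIs per class, extract features through the
pre-processing chain, select the top 20, and cross-validate the OvR-SVM
(2-fold × 3 repeats):

```bash
mitotexture simulate  --out rois --n-per-class 30 --seed 11
mitotexture extract   --images rois --manifest rois/manifest.csv \
                      --out features.csv --do-preprocess
mitotexture select    --table features.csv --out selected.csv --n-keep 20 --seed 11
mitotexture train-eval --table features.csv --out eval --model svm --seed 11
```

which prints:

```
accuracy: 0.956 +/- 0.013
confusion matrix (rows = true):
               fiber    puncta       rod
       fiber      81         0         9
      puncta       0        90         0
         rod       3         0        87
       fiber  precision 0.964  recall 0.900  f1 0.931
      puncta  precision 1.000  recall 1.000  f1 1.000
         rod  precision 0.906  recall 0.967  f1 0.935
       fiber  AUC 0.994 [0.988, 0.998]
      puncta  AUC 1.000 [1.000, 1.000]
         rod  AUC 0.992 [0.984, 0.998]
macro AUC: 0.995
```

Read this as: puncta are perfectly separable; essentially all remaining
error is fiber↔rod confusion (9 + 3 of the 12 misclassifications across the
pooled 270 test predictions), which is the expected hard case — both classes
share tubule width and intensity and differ mainly in connectivity. The
bracketed intervals are 95% percentile bootstrap CIs over 1000 resamples of
the out-of-fold scores.

`mitotexture stats --table features.csv --out stats.csv --groups fiber,puncta`
adds the per-feature MAD/Welch/Mann–Whitney comparison table.

## Library layout

- `mitotexture.image` / `mitotexture.preprocess` — TIFF I/O, `Image2D`, the pre-processing chain, ROI extraction
- `mitotexture.quantize` — gray-level discretization (fixed bin width / fixed bin count)
- `mitotexture.features` — the 93-feature suite and `FeatureTable` CSV I/O
- `mitotexture.mlcore` — scaling, RFE, decision tree, OvR-SVM
- `mitotexture.evaluation` — repeated stratified CV, reports, bootstrap ROC
- `mitotexture.groupstats` — MAD outliers, normality screening, two-group tests
- `mitotexture.synthgen` — synthetic morphology generator
- `mitotexture.cli` — the `mitotexture` command

See `docs/methods.md` for the modelling choices, conventions and known
limitations.
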