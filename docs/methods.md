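# Methods

## Pre-processing chain

Images pass through four stages, in floating point, with re-quantization to
the input bit depth only at the end (avoids cumulative rounding):

1. **Percentile saturation rescale.** The 1%/99% intensity quantiles
   (linear-interpolation estimator) are mapped linearly onto the full
   dynamic range; values outside are clipped. A constant image is returned
   unchanged.
2. **CLAHE.** The image is padded symmetrically to an 8×8 tile grid; each
   tile's 256-bin histogram is clipped at `clip × tile_pixel_count`
   (default clip 0.01), the excess is redistributed uniformly over all
   bins, and the tile's equalization map sends a bin to
   `full_scale × cdf`. Per-pixel output bilinearly interpolates the four
   surrounding tile maps; `clip = 1` reduces exactly to unclipped per-tile
   equalization. These are the classic MATLAB-style semantics, implemented
   directly because scikit-image's rank-based variant exposes a different
   clip parameterization.
3. **Adaptive Wiener filter** (3×3 window, symmetric padding): with local
   mean μ, local variance σ² and noise power ν² = mean of all local
   variances, `out = μ + max(σ²−ν², 0)/max(σ², ν²) · (x−μ)`. The noise
   power is estimated from the image itself.
4. **Gaussian smoothing**, σ = 0.5 px, kernel truncated at 4σ, symmetric
   boundaries (conserves mean intensity).

Boundary handling is symmetric (mirror) everywhere; it is the only choice
under which a constant image is a fixed point of every stage and means are
conserved.

## Discretization

All texture matrices share one gray-level assignment. The default dialect
is a fixed bin width of 25 intensity units:
`level(x) = floor(x/w) − floor(min/w) + 1`, anchored at the masked minimum,
so adding a multiple of the bin width to every pixel leaves levels
unchanged. A fixed-bin-count dialect (equal-width bins over the masked
range, top edge inclusive) is available in the config. Masks are supported
but default to all-true: the reference workflow analyzes whole rectangular
ROIs picked to be morphology-homogeneous.

## The 93-feature census

18 first-order + 24 GLCM + 14 GLDM + 16 GLRLM + 16 GLSZM + 5 NGTDM,
following the standard radiomics (IBSI-aligned) definitions. Conventions,
fixed for determinism and covered by tests:

- Logarithms are base 2 with ε = 2⁻⁵² added inside every log.
- Moments are population (biased); kurtosis is non-excess (normal ⇒ 3);
  skewness and kurtosis are 0 for a zero-variance ROI.
- First-order Entropy/Uniformity use the discretized histogram; the other
  first-order features use raw intensities. TotalEnergy scales Energy by
  the pixel area (1 if no pixel size is set).
- GLCM: distance 1, the four 2D offsets (0,1), (1,1), (1,0), (1,−1),
  symmetrized count + transpose, features computed per angle then
  averaged (matrices are not merged). Correlation is 1 when a marginal
  variance vanishes; MCC is 1 for a single-level ROI.
- GLRLM: runs are maximal collinear equal-level sequences over the same
  four directions; features are direction-averaged.
- GLSZM: zones are 8-connected components of equal level. Note a
  checkerboard therefore has two diagonal zones, not singletons.
- NGTDM: s_i sums |level − mean of valid 8-neighbors|; Coarseness is
  capped at 10⁶ when Σ p_i s_i = 0; Contrast/Busyness/Complexity/Strength
  are 0 when degenerate.
- GLDM: a neighbor is dependent when |Δlevel| ≤ α (default 0); the
  dependence size is j = d + 1 (the center counts itself).
- CSV column order: families firstorder, glcm, gldm, glrlm, glszm, ngtdm,
  alphabetical within family — fixed for diffability.

Every feature is verified against an independent brute-force
implementation (naive loops over pairs, runs, zones and neighborhoods in
`tests/oracles.py`) to 1e-9 relative tolerance on 100 random small ROIs.

## Selection and classifiers

RFE z-scores the features, drops zero-variance columns, and repeatedly
refits a one-vs-rest linear SVM, removing the lowest |coefficient| feature
(step 1) until 20 remain; stratified CV accuracy is optionally reported as
a function of retained-set size. Standardization is applied for the SVM
and for RFE — margin methods are scale-sensitive — and never for the
decision tree, which is scale-equivariant.

The decision tree is an axis-aligned Gini tree (scikit-learn defaults); in
two-class mode the positive class requires conditional probability > 0.5.
The OvR-SVM trains one binary margin classifier per class and predicts by
argmax of decision values (ties resolve to the earlier class in sorted
order); linear and RBF kernels are both first-class, RBF with C = 1,
gamma = "scale" being the default.

Cross-validation is repeated stratified k-fold with the scaler, the
selector and the model all refit inside each training fold — nothing is
learned from a test fold. Reference schemes: 10-fold × 1 for the tree,
2-fold × 3 for the SVM. Accuracy is reported as mean ± sd over all folds
of all repeats; confusion matrices are pooled. ROC analysis is one-vs-rest
on decision values; AUC confidence intervals are percentile intervals over
1000 bootstrap resamples stratified by class (so no resample is
single-class); macro AUC is the unweighted mean of per-class AUCs.

## Group statistics

Per feature and per group, values outside median ± 2.1·MAD are replaced
with NaN (MAD is the raw median absolute deviation, no 1.4826 factor —
the fence formula uses it directly). The rule is applied once, not
iterated. Each group is then screened with Shapiro–Wilk; both groups
passing (p > α) selects Welch's unequal-variance t-test, anything else the
two-sided Mann–Whitney U (exact when combined n ≤ 20 without ties, normal
approximation with tie correction otherwise). Significance is p < 0.05,
with no multiple-testing correction by default (a Benjamini–Hochberg
option exists but is off).

**Calibration caveat.** The Welch/Mann–Whitney stage is well calibrated:
under the null, ~4–5% of 1000 simulated features are flagged. The MAD
trimming stage, however, is *anticonservative* when chained into the
tests: for normal data the k = 2.1 raw-MAD fence sits at ±1.42σ, trimming
~16% of each sample, and sample-dependent trimming shrinks the variance
estimate without a Winsorized correction — the measured null rate of the
full chain is ~25%. Users comparing many features should treat
post-trimming p-values as screening scores, enable the BH option, or widen
k. The implementation keeps the described procedure faithfully.

## Synthetic generator

The generator emulates the three morphology classes on a 69×69 8-bit
canvas over background 0.12 of dynamic range:

- **puncta** — 8–20 Gaussian spots (σ 1.2–2.2 px, amplitude 0.6–1.0),
  centers ≥ 8 px apart;
- **fibers** — branching random-walk skeletons (2–5 seeds, branch
  probability 0.05/step, heading jitter sd 0.25 rad) dilated to ~3 px
  tubules and smoothed; the skeleton pixel budget (120–360 px) is drawn
  from the same range a rod ROI's total segment length spans, so fibers
  and rods overlap in coverage and differ chiefly in connectivity;
- **rods** — 5–12 straight segments (length 10–25 px, ~3 px wide),
  mutually disjoint with a 2 px halo.

Noise is Poisson shot noise (photon budget 150 counts at full signal) plus
additive Gaussian read noise (sd 0.05 of dynamic range) — the standard
confocal approximation. A "treated" condition draws morphologies from a
fragmentation-shifted mixture (fiber/rod/puncta 0.45/0.30/0.25 untreated
vs 0.20/0.30/0.50 treated). All draws flow from one `numpy` Generator per
dataset, so outputs are bit-reproducible under a seed.

What the generator does *not* emulate: PSF anisotropy, depth-dependent
background, membrane-potential-dependent staining variation, and mixed
morphologies inside one ROI. Passing tests therefore demonstrate that the
pipeline recovers the designed texture differences, not field performance
on real micrographs.

The benchmark conditions used by the test suite are 30 ROIs per class at
the default noise with one fixed seed; the classification benchmark runs
the full preprocess → extract chain, while the morphology-direction checks
(long/short-run emphasis, kurtosis, skewness, contrast orderings) are
measured on raw generated ROIs — CLAHE, by design, flattens exactly the
local-homogeneity differences those orderings describe.

## Known limitations

- The tree-vs-SVM ranking seen on real confocal data (SVM ahead) does not
  reproduce on the synthetic benchmark: the synthetic class signal
  concentrates in a few nearly axis-separable features, which favors
  axis-aligned trees. The comparison machinery itself is fully supported.
- 2D only; no wavelet/LoG/Gabor filter banks; no shape features; no
  automatic ROI detection (ROIs are supplied or simulated).
- Exact Mann–Whitney p-values are limited to small samples without ties;
  elsewhere the normal approximation is used.
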