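# Methods

## Overview

`xlung` studies whether quantitative CT descriptors of interstitial lung
disease (ILD) — and classifiers built from them — transfer between two
acquisition domains: a small-animal microCT-like domain (the discovery
setting) and a clinical HRCT-like domain (the validation setting). Because no
deposited scans accompany the problem, the package ships a synthetic phantom
generator that reproduces the *statistical* structure of diseased and healthy
lung CT; every downstream stage (feature extraction, stability filtering,
univariate screening, multivariate transfer modeling) is exercised end to end
on those phantoms.

## Image preparation

Volumes are resampled to an isotropic grid (0.15 mm for the microCT-like
domain, 2.75 mm for the HRCT-like domain) with trilinear interpolation; masks
are interpolated linearly and thresholded at 0.5, which avoids the
nearest-neighbour aliasing of thin lung margins. The ROI is then re-segmented
to HU in [−1000, 200], bounds inclusive. Gray levels are discretized with a
fixed bin size of 50 HU anchored at −1000 HU — anchoring at the lower
re-segmentation bound keeps level k meaning the same HU interval for every
subject and domain, which is what cross-domain comparison requires. With
this window and width the level count is fixed at 24. Bins are [edge, edge)
except the last, which is closed, so the window's top edge falls in bin 24
rather than creating a 25th level. The interpolation kernel and bin anchor
are configurable; the values above are the defaults used everywhere.

## Feature bank

154 features per subject: 17 first-order histogram statistics on raw HU, and
137 texture features from six gray-level matrices (GLCM, GLRLM, GLSZM, GLDZM,
NGLDM, NGTDM) on the discretized ROI. GLCM and GLRLM are featurized under two
aggregation schemes — *averaged* (features per 3D direction, then averaged)
and *merged* (count matrices summed over directions, then featurized) —
giving 26×2 + 16×2 + 16 + 16 + 16 + 5 = 137.

Conventions, fixed for reproducibility and tested against brute-force
enumeration oracles:

- 26-connectivity (Chebyshev distance 1) everywhere; 13 unique direction
  vectors for GLCM/GLRLM; co-occurrence accumulated symmetrically.
- GLDZM zone distance: minimum Chebyshev distance from any zone voxel to the
  nearest non-ROI voxel, the image border counting as outside, minimum 1.
- NGLDM coarseness parameter alpha = 0; the center voxel is never its own
  neighbour, so dependence counts range 0–26 and emphasis weights use
  (count + 1) to stay finite.
- Kurtosis is Pearson (non-excess): a Gaussian scores 3. Skewness is Fisher.
- Texture features are computed from probability-normalized matrices;
  count-based non-uniformities use raw counts.
- Degenerate single-level ROIs take their defined limits (entropies 0,
  normalized non-uniformities 1, GLCM correlation 1) rather than NaN.

Feature identities are stable V-codes from a declarative registry (V1 mean,
V2 standard deviation, V4 skewness, V5 kurtosis, V16 root mean square, V108
GLSZM gray-level non-uniformity normalized, V141 NGLDM dependence count
non-uniformity, among others). The registry is data-driven so the feature
set can be swapped without touching the math. The 26th GLCM feature beyond
the common 25-feature set is Haralick's maximal correlation coefficient.

## Synthetic phantoms

Each phantom is a two-lobe ellipsoidal lung inside a soft-tissue body on a
64³ grid (microCT-like, anisotropic 0.14/0.18 mm spacing) or 96³ grid
(HRCT-like, 2.5/3.0 mm); grid sizes were chosen for desk-scale runtime.
Within-lung HU mixes four components:

1. **Parenchyma** — a positively skewed shifted gamma (default mean −750 HU,
   SD 80 HU, skewness 1.5): the air-dominated healthy histogram.
2. **Vessels/airway walls** — a sparse fraction (1.5%) of voxels at a fixed
   +400 HU offset above the subject's parenchymal mean. This produces the
   healthy lung's heavy right tail. The offset is mean-relative so that a
   subject's baseline attenuation does not mechanically couple to its
   skewness.
3. **Heavy-tail floor** — a small fraction (3%) of parenchymal deviations
   inflated 3×, a symmetric component that drives kurtosis
   semi-independently of skewness.
4. **Texture patches** — Gaussian-smoothed binary noise thresholded to a
   per-subject coverage fraction, filled with N(−520, 60) HU. Contiguous
   patches create genuine zone/dependence texture, not just a histogram
   shift. Every subject carries a benign rate (3%, lognormally varying —
   scarring, gravity-dependent atelectasis); ILD adds
   `texture_patch_rate × severity` (12% at full severity) on top. The benign
   component is essential: without it, zone features separate the classes
   perfectly and nothing about model transfer can be observed.

Disease severity is a per-subject uniform draw on [0.3, 1] (an early-to-
established fibrosis spectrum, mirroring multi-time-point discovery cohorts).
Severity scales the parenchymal mean shift (+90 HU at full severity), the
spread increase (×1.9), a mild symmetrization of the parenchymal skew (×0.9),
the suppression of the heavy-tail floor (−25%), and the added patch coverage
(12%). Between-subject heterogeneity (baseline mean SD 50 HU, spread SD 17%,
skewness SD 33%, lognormal vessel, tail and patch-fraction variation) keeps
cohorts realistically overlapping: without it every classifier sits at
AUC 1.0 and nothing about transfer can be observed.

The net effect directions are the clinically expected ones and are asserted
as properties: ILD raises within-lung mean and SD and lowers skewness and
kurtosis, and raises zone/dependence non-uniformity through the blobs.

The two domains share all disease-effect parameters (a pure covariate
shift): they differ in voxel spacing, additive noise (15 vs 30 HU), a global
+60 HU bias in the HRCT-like domain, and larger patient-cohort heterogeneity
(baseline SD 65 HU, spread SD 27%). These distortions move each feature
differently, which is what degrades a frozen multivariate model in the
target domain while leaving the underlying signature intact.

Default effect sizes were calibrated once, at design time, to place the
cohorts in the regime the emulated study occupies — source-domain mean-
intensity AUC ≈ 0.9, near-but-not-perfect multivariate separation, degraded
frozen-model transfer — and to give the four intensity moments comparable,
jointly identifiable effects (the population discriminant direction has the
expected signs with margin). They are fixed defaults, not tuning knobs.

**What the generator does not emulate:** airway/vessel anatomy, respiratory
motion, reconstruction-kernel texture, scanner-specific noise power spectra,
partial-volume effects at lobe boundaries, and disease sub-phenotypes
(ground glass vs honeycombing). Passing tests therefore demonstrate that the
pipeline's statistics and transfer logic behave correctly on data with the
right moment and texture structure — not that the features would achieve any
particular performance on real scans.

## Observer perturbation

Delineation variability is emulated by thresholding the mask's signed
Euclidean distance against a smooth random field clipped to ±1, giving a
boundary displacement bounded by `boundary_jitter_mm`, plus an optional
single-voxel erosion/dilation. A Dice ≥ 0.5 bound is enforced (retry with
halved jitter, then error). Intra-observer repeats and inter-observer masks
(default 2 repeats, 3 observers, on a 15-case subset per domain) are
independent perturbations of the true mask; the underlying volume is never
modified. The default perturbation (0.1 mm jitter, 2% single-voxel
erosion/dilation) emulates careful expert delineation: most features remain
stable and the occasional whole-shell morphological event dominates whatever
instability appears.

## Stability filtering

Robustness is the two-way mixed, consistency, single-rater intraclass
correlation — ICC(3,1) = (MS_R − MS_E)/(MS_R + (k−1)MS_E). Consistency (not
absolute agreement) is the right variant for delineation studies: a rater
whose contours are systematically larger shifts every feature additively and
should not mark features unstable. A feature is retained only if ICC ≥ 0.75
in all four (intra/inter × domain) cells. Two edge cases: raters in perfect
agreement are consistent by definition (ICC = 1, even for a feature constant
across subjects, e.g. NGLDM dependence-count percentage); raters that
disagree when subjects do not differ give an undefined ICC, treated as
unstable. Aggregation redundancy between averaged and merged GLCM/GLRLM
variants is summarized as the family median of per-feature two-rater
consistency ICCs; at the default threshold 0.8 the merged variant is dropped
(keeping averaged; both choices are configurable).

## Univariate screening and cross-domain correlation

Per-feature discriminative power is the directional AUC — P(value in ILD >
value in control), the normalized Mann–Whitney U with mid-rank tie credit —
reported without flipping below 0.5, so that opposite effect directions in
the two domains remain visible. Cross-domain transferability of univariate
power is the Pearson correlation of the per-feature AUC vectors, overall and
per family.

## Transfer modeling

Three architectures: MEAN (logistic regression on V1), MSSK (logistic
regression on V1, V2, V4, V5), and ML (embedded feature selection: greedy
correlation pruning at a tunable Pearson threshold keeping the feature with
the better train-fold AUC from each correlated pair, an L1-logistic selector
whose top-k coefficients feed the final L2 classifier). Tuning runs 4-times
repeated 5-fold cross-validation with randomized hyperparameter search
(correlation threshold ∈ [0.6, 0.99], k ∈ [1, 10], L2 strength C log-uniform
on [1e−3, 1e3]; 500 samples in total by default, maximizing mean CV AUC),
then refits the winning configuration on all source data. Standardization
statistics always come from training folds only; the target domain never
influences tuning.

Testing applies the frozen model — including source standardization — to the
target domain and reports AUC with a 2000-resample stratified bootstrap
percentile CI. Re-optimization re-estimates the standardization, the
regularization strength (same randomized search), and the logistic weights in
the target domain under the same repeated CV, with the source-selected
features frozen — the signature transfers; the weights do not have to. Operating-
point diagnostics (TPR, TNR, PPV, NPV, LR±) are taken at the cutoff
maximizing Youden's J over observed score thresholds, ties resolved toward
higher specificity then higher cutoff; the cutoff is chosen on the test
scores themselves, which is optimistic and is reported as such. LR+ is +inf
when TNR = 1; bootstrap CIs treat infinities as such.

The coefficient-direction report for linear models gives the sign of each
standardized coefficient. When aggregating over modeling seeds, coefficient
vectors are L2-normalized before averaging so a single weakly-regularized
(large-C) fit cannot dominate the average direction.

## Problem sizes and numerical choices

Desk-scale defaults used by the tests and the acceptance script: the
transfer study uses one cohort of 40 control + 40 ILD subjects per domain,
extracted once, with 10 modeling seeds and 60 randomized hyperparameter
samples per seed; the stability study uses 12–15 cases per domain with
2 repeats × 3 observers; oracle cross-checks use 100 random 4³ ROIs, 1000
AUC fuzz cases, and 200 ICC/Youden cases. The pipeline smoke configuration
(24³ grids, 8 subjects per arm) runs end to end in well under a minute.
Seeds fan out from a single global seed through `numpy.random.SeedSequence`,
making every artifact byte-reproducible.

## Known limitations

- The Youden cutoff is estimated on the same target scores it characterizes.
- ICC confidence intervals are not computed (stability is a point-estimate
  filter, as in the emulated design).
- Partial (multivariate) coefficient signs of collinear moment features are
  intrinsically unstable at n = 80 when the classifier is weakly
  regularized; the seed-averaged direction is the stable summary, and the
  per-seed sign agreement is reported alongside it.
- The ML architecture's tree-boosting selector variant
  (`ModelSpec(selector="tree")`) uses gradient-boosting importances with an
  otherwise identical pipeline; the logistic selector is the default.
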