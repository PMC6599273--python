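# Methods

## Problem and model

Screen-detected lung cancers split into biologically *indolent* lesions,
for which treatment may constitute overdiagnosis, and *aggressive* lesions.
Under an exponential-growth assumption the volume-doubling time over a
screening interval of `T` days with volumes `V0` and `Vi` is

    VDT = ln 2 · T / ln(Vi / V0)

and the package classifies an interval as aggressive iff `0 < VDT < 400`
days. The 400-day rule follows the screening literature's overdiagnosis
convention. Boundary and degenerate cases are resolved explicitly:
`VDT = 400` exactly is indolent (400 days *or more* is the slow-growing
range); an unchanged volume yields an infinite-VDT sentinel, classified
indolent; a shrinking lesion yields a negative VDT, also indolent — a
non-growing lesion cannot be fast-growing. A patient whose consecutive
intervals disagree receives the descriptive label *mixed* with the switch
direction recorded; for modelling, each interval enters individually with
its own label, and the features come from the interval's baseline scan.
Volumes feeding the VDT are taken from the lung-window mask, which defines
the whole lesion.

## Window masks and the difference region

A CT window with width `W` and level `L` maps HU to display gray
`clip((HU − (L − W/2)) / W, 0, 1)`. The two canonical chest windows are
lung (W 1500 / L −400) and mediastinal (W 400 / L 40). Part-solid nodules
show their full extent (solid core + ground-glass rim) in the lung window
but only the solid core in the mediastinal window; the voxelwise
*difference region* `DR = LW ∧ ¬MW` isolates the non-solid habitat.

Segmentation is a deterministic threshold surrogate for radiologist
delineation: the 26-connected supra-threshold component containing a seed
point, followed by one binary-closing pass with a 3×3×3 structuring
element. Default thresholds: −750 HU under the lung window (captures
ground-glass, excludes −850 HU parenchyma) and −160 HU — the mediastinal
window floor, i.e. any tissue rendered non-black — under the mediastinal
window. Both are overridable. Because −160 > −750 the mediastinal mask is
nested in the lung-window mask (enforced after closing), so
`|DR| = |LW| − |MW|` holds exactly. Semi-automatic tools segmenting the two
windows independently need not produce nested masks; the surrogate's
nesting is a deliberate simplification, as is the absence of the manual
edits radiologists apply to roughly one in twelve nodules for pleural or
vascular attachment.

## The 364-feature extractor

Each mask yields exactly 364 features: 209 IBSI-style, 125 Laws, 30
wavelet. The catalogue order is contractual (`F<i>` never changes meaning)
and pins the anchor indices F8 (10th percentile), F19 (root mean square),
F44 (IVH volume at intensity fraction 90), F87 (intensity-weighted centre
of mass, z), F296 (a level-2 wavelet sub-band entropy) and F311 (voxel
dimension x). Those anchors force the families to interleave: first-order,
histogram, IVH, morphology, distance-1 GLCM, GLRLM and GLSZM occupy
F1–F141; Laws F142–F266; wavelet F267–F296; GLDM, grid metadata, NGTDM,
distance-2 GLCM, merged-aggregation GLRLM and histogram-gradient features
fill F297–F364. Identities beyond the anchors are fixed by the shipped
catalogue; each name states its definition family and the module docstrings
give the formulas.

Numerical choices:

- **Discretization**: fixed bin count 32 over the in-mask HU range for all
  histogram/texture families; a constant region maps to level 1.
- **Directional aggregation**: GLCM and GLRLM use all 13 unique 3D
  directions at distance 1 (GLCM also distance 2); the primary GLRLM block
  averages features over directions, a second block merges matrices first.
- **Laws energies**: all 5³ separable filters from L5/E5/S5/W5/R5, applied
  along (z, y, x) with reflect boundaries; feature = mean |response| over
  mask voxels. Requires a ≥5-voxel bounding box per axis.
- **Wavelet**: two-level 3D stationary (undecimated) `coif1` transform with
  variance-preserving normalization, so sub-bands stay on the voxel grid
  (no mask resampling) and sub-band energies sum to the input energy
  exactly. 15 sub-bands (7 level-1 detail, level-2 approximation, 7 level-2
  detail) × {in-mask mean-square energy, Shannon entropy of the in-mask
  squared-coefficient distribution}. Requires a ≥8-voxel bounding box.
- **Morphology**: marching-cubes mesh surface after a light (σ 0.8 voxel)
  Gaussian smoothing of the binary mask, which suppresses the staircase
  overestimate of meshing hard voxel boundaries; axis lengths from the
  voxel-cloud principal components; convex hull via Qhull. The
  intensity-weighted centre of mass weights voxels by `HU + 1024`
  (attenuation above air) so weights stay positive; these features are
  intentionally not invariant to artificial HU offsets, unlike the purely
  geometric ones.
- **Resampling**: none by default (phantoms are isotropic); optional
  trilinear resampling to 1 mm for anisotropic input.
- **Missing values**: an empty mask emits an all-missing vector with a
  warning (legitimate: purely ground-glass nodules have empty
  mediastinal-window masks); families whose minimum support exceeds the
  mask emit NaN and are logged. Extraction is restricted to the mask
  bounding box plus an 8-voxel margin, so features depend only on voxels in
  or near the mask.

## Selection and modelling chain

Feature selection runs four nested stages: (1) pooled-variance Student's
t-test, keep `p < 0.05` (Welch optional; constant features dropped with a
logged reason); (2) per-feature AUROC under 200 stratified bootstrap
resamples, keep mean AUROC ≥ 0.5 — the AUROC is the rank-sum statistic with
tie credit and is deliberately *not* orientation-flipped, otherwise the 0.5
floor would be vacuous; (3) Pearson pruning: connected components of the
`|r| ≥ 0.8` graph, keeping per component the feature with the largest mean
bootstrap AUROC (connected components rather than greedy pairwise order
make the result order-independent); (4) backward-stepwise logistic
elimination, removing the worst Wald `p > 0.10` covariate and re-admitting
an excluded covariate when its refit p-value is below 0.05 ("entry" is
tested by refitting the candidate, a standard stepwise reading of an
otherwise ambiguous rule). Cycles are prevented by tracking visited
covariate sets.

(Quasi-)separation is detected from diverging coefficients or standard
errors, flagged, and handled rather than fatal: the capped-iteration fit is
reported, and during elimination the removal decision switches to
likelihood-ratio p-values, since Wald statistics collapse under separation
and would otherwise discard a perfectly separating covariate.

Three logistic models are fitted — lung-window features, difference-region
features, combined — each defining a *radiomics score* (its linear
predictor); refitting a one-covariate logistic model on the score
reproduces the original probabilities exactly, which is tested. Each score
is then augmented with sex and COPD. Performance is the rank-sum AUROC with
a stratified-bootstrap percentile CI (default 5000 resamples for model
validation, 200 for feature screening; the pipeline demo uses 500 to keep
the one-command run quick) plus accuracy, sensitivity and specificity at
the Youden-optimal threshold of the apparent ROC, with *aggressive* as the
positive class (configurable). Nomograms map each covariate to
`100·β·(x − x_ref)/K` points, `x_ref` the observed-range end minimizing the
linear predictor and `K = max |β|·range`, so the strongest covariate spans
exactly 0–100 and total points invert to probability through the logit.

## Synthetic phantoms: what they emulate and what they do not

Each phantom nodule is an ellipsoidal solid core (HU 20–60) inside a
concentric rim (HU −650 to −350) whose boundary radius is perturbed by
low-order spherical-harmonic-like terms (amplitude 0.12), embedded in
−850 HU parenchyma; one Gaussian pass (σ 0.5 voxel) approximates
partial-volume blur before additive Gaussian noise (σ 20 HU). Growth is
exact isotropic scaling at an assigned VDT, so the volume contract
`V1/V0 = 2^(Δt/VDT)` is checkable to voxelization error (≤5% for ≥200-voxel
nodules). Defaults mirror the screening-cohort structure the analysis
targets: 26% indolent; class VDTs log-normal with medians 583 vs 148 days,
truncated at the 400-day rule (aggressive also truncated below at 80 days
so growth stays within the default 48³ grid); screening intervals uniform
on 300–430 days; 17/36 of three-timepoint patients switch class between
intervals by drawing the second interval's VDT from the opposite class;
female frequency 70%/31.17% and COPD 0%/20.78% in indolent/aggressive
patients; baseline volumes log-uniform on 250–700 mm³. The planted radiomic
effect is the class-conditional rim-to-total volume fraction,
Beta(8,4) for indolent vs Beta(4,8) for aggressive — indolent lesions are
predominantly ground-glass, which is what makes the difference region
informative.

Phantoms deliberately omit: scanner/kernel heterogeneity, anisotropic
voxels, pleural/vascular attachment, non-exponential growth, and
real-lesion texture beyond white noise. Passing tests therefore establish
that the machinery recovers planted effects under its own assumptions, not
that the specific published effect sizes transfer to clinical images — the
published model coefficients depend on non-redistributable screening images
and are not reproduction targets here.

## Problem sizes used in the checks

The end-to-end recovery check generates 150-nodule cohorts (two timepoints,
one interval per nodule) over 10 seeds, runs the full selection + modelling
chain on the lung-window and difference-region feature tables, and asserts
apparent combined-model AUROC > 0.75 at the fixed first seed with the mean
ordering combined ≥ difference-region ≥ 0.5 across seeds. Statistical
property suites use 1000 null features for the t-test type-I rate, 200
bootstrap resamples for per-feature AUROC, and brute-force oracles (voxel
loops, exhaustive pair counting, naive connected components, step-by-step
stepwise replay) for every counting identity.

## Known limitations

- The threshold-surrogate segmentation enforces mediastinal⊂lung nesting;
  independently segmented clinical masks need not nest.
- The 30 wavelet identities and the naming scheme behind "P1L2C10"-style
  labels follow the package's own catalogue; only the count, the level-2
  anchor position and the two-level sub-band structure are contractual.
- Backward-stepwise p-value selection is known to produce optimistic
  apparent performance; the bootstrap CI here is internal validation, not
  optimism correction (an optimism-corrected variant is a natural
  extension).
- Phantom AUROCs run higher than clinical values because the planted effect
  is clean; the recovery test asserts ordering and a floor, not published
  magnitudes.
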