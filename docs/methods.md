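# Methods

## Scope and model

The package reproduces a radiomics protocol for WHO glioma grading from
diffusion-weighted MRI: ADC parametric maps, tumor-ROI texture features
(histogram moments + grey-level co-occurrence statistics), SMOTE class
balancing, ANOVA F-test feature selection, and a cross-validated,
hyperparameter-tuned random-forest classifier of three grade groups
(GBM = 0, HGG = 1, LGG = 2). The clinical dataset behind the original
protocol is private; a synthetic phantom cohort with the same composition
and the same qualitative class structure stands in for it, so the whole
chain is testable offline.

## ADC estimation

Per pixel, `ADC = mean_i[-ln(S_i/S_0)/b_i]` over the b>0 images. Two
choices deserve note:

* **Sign.** The raw log-ratio `ln(S_i/S_0)/b_i` is negative wherever signal
  attenuates; the implementation uses the standard negated form so ADC is
  positive for attenuating tissue. This matches the universal convention
  (and the interpretation "high ADC = high diffusivity" the protocol
  itself relies on).
* **Multi-b averaging.** Summing per-b estimates without dividing would
  scale the result by the number of b-values; the mean keeps units mm²/s
  for any number of diffusion-weighted images. For the single-pair
  b=0/1000 case the two readings coincide up to the sign convention.

Pixels with non-positive signal in any image are flagged invalid (value 0,
excluded from the ROI before any feature computation).

## Quantization and GLCM

Grey-level quantization is per-ROI min–max linear binning into `n_levels`
equal-width bins (default 64, configurable 8–256; 64 keeps the matrix
reasonably dense for ROIs of a few hundred pixels). The mapping is
monotone, so all GLCM features are invariant to monotone affine transforms
of the underlying diffusivities — tests assert this.

Co-occurrences are accumulated at unit distance over the four offsets
(0,1), (−1,1), (−1,0), (−1,−1) (0°, 45°, 90°, 135°) and summed, counting
only pairs with both pixels valid and in-ROI. The matrix is **not
symmetrized by default**: the reference protocol reports different
selection scores for the row- and column-marginal means, which is only
possible for an unsymmetrized matrix. A `symmetric` flag restores the
common convention (under which the two marginals coincide — asserted in
tests). Entropy uses the natural log with 0·ln 0 := 0. Correlation is
returned as 0, flagged, when a marginal variance vanishes (single-entry
matrices). Cluster shade is computed verbatim from its third-power
definition and not clamped to any range.

## Moments

Central moments use equal pixel weights 1/N; skewness is m₃/m₂^1.5 and
kurtosis the non-excess m₄/m₂² (normal population → 3). A zero-range ROI
reports skewness = kurtosis = 0 with a `degenerate` flag instead of
raising, so constant phantoms traverse the pipeline; the range check (not
the computed m₂) decides degeneracy because summation round-off can leave
a denormal m₂ on constant input.

## Phantom cohort generator

What it emulates: the study composition (88 subjects, 57 M / 31 F, ages
8–90 uniform; 722 slices split 431/182/109 GBM/HGG/LGG; 124×124 matrix;
b = 0 and 1000 s/mm²) and the class structure the analysis assumes —
lower, more heterogeneous diffusivity in more aggressive tumors.

Mechanism per slice: a Gaussian random field (white noise smoothed by a
Gaussian kernel of the class correlation length, rescaled to the class
marginal sd, shifted to the class mean plus a per-subject offset), clipped
positive; an elliptical ROI (semi-axes 5–15 px, random orientation,
area forced into 80–600 px with bounded retries); the forward DWI model
S_b = S₀·exp(−b·ADC) with additive Gaussian noise on each magnitude image.

Defaults (chosen once, from physiological glioma ADC ranges, and frozen):

| parameter | GBM | HGG | LGG | unit |
|---|---|---|---|---|
| class ADC mean | 0.80e-3 | 1.00e-3 | 1.30e-3 | mm²/s |
| class ADC marginal sd | 0.22e-3 | 0.18e-3 | 0.15e-3 | mm²/s |
| texture correlation length | 2 | 3 | 4 | px |

with per-subject offset sd 0.05×10⁻³ mm²/s, S₀ = 1000, DWI noise sd 5
(≈0.5 % of S₀), one ROI per slice (multiplicity configurable),
demographics carrying no class signal by default (an `age_class_shift`
knob exists for power studies).

What it does **not** emulate: anatomy, 3D tumor continuity across slices,
Rician noise statistics (additive Gaussian is used for simplicity at this
scale), scanner/site effects, and radiologist ROI variability. Passing
tests therefore demonstrate the correctness and stability of the
*pipeline*, not clinical-grade performance; absolute accuracies on the
phantom (≈0.92) are a property of the generator's class separation, not a
clinical claim.

## Preparation protocol

* **SMOTE** is implemented from its definition (k = 5 neighbours, Euclidean
  distance, seeded RNG); every class is topped up to the majority size.
* **Order of operations**: mode `paper` balances the whole table *before*
  the 70:30 stratified split (random state 42), faithful to the reference
  protocol but leaking synthetic neighbours across the split; mode `sound`
  balances the training fold only. Both are first-class; the default is
  `paper` so the bookkeeping (905/388 rows, test supports 130/129/129)
  reproduces exactly.
* **Split rounding** follows the standard stratified splitter (total test
  size ⌈0.3·n⌉, per-class error ≤ 1 row), which is what yields supports
  {130,129,129} for a balanced 431×3 table.
* **Standardization** defaults to z-scoring (population sd) fitted on the
  training fold only; min–max to [0,1] is available. Constant features are
  flagged and emitted as zeros.
* **ANOVA selection** computes the one-way F from its sum-of-squares
  definition and drops the `drop_count` = 3 lowest-F features (ties broken
  by column order). On the phantom the dropped trio is skewness, cluster
  shade and age — the phantom's age is uninformative by design, whereas
  the clinical analogue found gender, GLCM energy and correlation weakest
  on its data; the selection is recomputed on whatever data the pipeline
  is run on. Whether selection ran before or after balancing is ambiguous
  in the source protocol; here it runs after, on the training portion.

## Modeling protocol

Stratified 10-fold CV (shuffled, seeded) scores seven classifiers by mean
fold accuracy: k-NN, LDA, Gaussian naive Bayes, decision tree, SVM, random
forest, logistic regression (library implementations, fixed random states).
The base model is a random forest at library defaults; tuning searches
n_estimators 100–1000, max_depth 10–110 (11 steps), min_samples_split
{2,5,10}, min_samples_leaf {1,2,4}, max_features = √p, bootstrap {T,F},
either exhaustively (`grid`) or by seeded randomized draws over the integer
ranges (`random`, default — the reference protocol's reported optimum,
108 trees, is not on its own printed grid, indicating a randomized search;
that optimum ships as the preset `PAPER_TUNED`). The search loop is
explicit so exact ties in mean CV accuracy resolve toward fewer trees,
then shallower depth. min_samples_leaf values were unstated upstream;
{1,2,4} is the conventional grid.

**Winner stability.** Because the top algorithms can sit within fold noise
of one another, "the CV winner is stable" is operationalized as: over the
fold-shuffle seeds 0–9, a unique modal winner takes at least 8 of 10
seeds, and wherever it does not win outright its mean accuracy lies within
one fold-level standard error (sd/√K) of the top score. On the default
phantom the random forest wins 9/10 seeds and sits 0.002 (SE ≈ 0.010)
behind the SVM on the remaining one.

Evaluation reports accuracy, per-class precision/recall/F1 (stored at full
precision, rendered at 2 decimals), 3×3 confusion counts and one-vs-rest
ROC AUC from predicted probabilities. `report_from_confusion` rebuilds the
metric set implied by a confusion matrix alone, which is how the reference
protocol's printed counts (112/130, 109/129, 121/129 correct → 88.14 %
accuracy, 11.86 % error, LGG recall 0.94) are verified as arithmetic.

## Numerical and degenerate-input conventions

* Constant ROI → levels all 0; single-entry GLCM → energy 1, entropy 0,
  contrast 0, homogeneity 1, correlation 0 (flagged).
* One-pixel or disconnected ROI with no valid pairs → explicit error.
* ANOVA: overall-constant feature → F = 0 (`constant` flag); zero
  within-class variance with distinct means → F = +inf
  (`perfect-separator` flag).
* CSV round-trips write floats at %.17g and parse with round-trip
  precision, so feature tables survive disk exactly.
* All RNG flows through `numpy.random.default_rng` seeded from one config
  value; a fixed seed gives a bit-identical cohort, preparation and model
  report (asserted by hash comparison of a rerun).

## Problem sizes in the test suite

Unit tests run on reduced cohorts (tens of slices, 48–64 px images); the
acceptance-style tests use the full default cohort (722 slices) once per
session, 10-fold CV over ten seeds, and a reduced randomized tuning budget
(8 draws, 5 folds) — the tuning budget is a protocol knob, and a small
budget suffices to demonstrate the search and the accuracy floor. Oracle
equivalence runs 1000 random quantized ROIs against naive double-loop
references at 1e-12 relative tolerance.

## Known limitations

* The phantom's GLCM features carry weaker class signal than mean ADC by
  construction; feature-importance conclusions do not transfer to clinical
  data.
* `paper` mode's SMOTE-before-split leaks information into the test set;
  use `sound` mode for honest generalization estimates (the package keeps
  both precisely to make that difference measurable).
* Rician noise, 3D context and multi-ROI pooling strategies are out of
  scope.
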