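# Methods

`snpnoise` studies how random phenotyping errors — binary class labels
flipped uniformly at random — degrade SNP-based genomic classification of a
binary plant trait. Because the sugar-beet panel that motivates the study is
not publicly deposited, the package ships a synthetic-population generator
that reproduces the panel's documented statistical structure, and every
downstream stage (QC, noise injection, classification, evaluation) runs on
that fixture end to end.

## Synthetic population

The generator emulates a selected sugar-beet panel: 123 plants from 18
lines — 15 high-root-vigor lines carrying 99 plants and 3 low-vigor lines
carrying 24 — genotyped at 192 biallelic SNPs assigned round-robin to the 9
chromosomes (21–22 per chromosome). Plants are allocated to lines as evenly
as possible (remainders go to the first lines); each line carries exactly
one true vigor class.

The genotype–phenotype mechanism is a line-level allele-frequency-contrast
model. The panel's true architecture is unknown, so the generator adopts a
transparent stand-in chosen once:

- **Causal markers** (default 40): allele frequency 0.9 in high-vigor lines
  and 0.1 in low-vigor lines. Forty markers leave room for 30-marker
  informative subsets to retain essentially all of the class signal.
- **Background markers**: a per-marker base frequency drawn from a symmetric
  Beta(2, 2), clipped to [0.1, 0.9] so no background marker drifts into the
  rare-variant range, then per-line frequencies drawn from a
  Beta(cb, c(1−b)) around the base with concentration c = 30. The drift
  creates the within-class line clustering expected of an inbred-derived
  panel (plants' nearest genotype neighbours are their line-mates).
- Dosages are Binomial(2, p_line,marker) draws coded 0/1/2.

Root elongation is drawn per plant from a normal with class mean 12.9
(high) or 2.6 (low) mm/day and common SD 1.5 mm/day, truncated to the
correct side of the dichotomization threshold 7.75 mm/day (the midpoint of
the class means). Truncation makes the 99/24 label counts exact for every
seed; at SD 1.5 the truncation removes only ~3·10⁻⁴ of the mass, so the
distribution remains effectively the stated bimodal normal mixture. With 40
causal markers at a 0.8 frequency contrast the two classes are linearly
separable in genotype space by construction (verified by a hard-margin
linear SVM reaching zero training error).

Two fixture-construction stages overlay the panel's data-quality blemishes:

- **Missingness**: exactly 738 cells (3.1 % of 123 × 192) are masked. One
  designated marker (outside the causal and rare sets) receives 21 missing
  calls, putting its call-rate at 102/123 ≈ 0.829 ≤ 0.85. The remaining 717
  cells are placed by a seeded permutation over the other markers' cells
  under two caps: at most 18 missing calls per other marker (so exactly one
  marker falls below the call-rate threshold, for every seed) and at most
  half of any sample's genotypes. The placement is uniform apart from these
  rarely binding caps.
- **Rare markers**: 16 markers disjoint from the causal set are overwritten
  as 1–6 heterozygous carriers (all other plants homozygous reference), so
  their minor-allele count is at most 6 of 246 (MAF ≤ 0.0244 ≤ 2.5 %).

What the generator does **not** emulate: linkage disequilibrium decay,
recombination maps, physical marker positions, pedigree structure, and any
polygenic architecture more diffuse than the frequency-contrast model.
Passing tests therefore demonstrate the pipeline's behaviour under a
strongly structured, cleanly separable population — not performance on real
panels, where signal is weaker and correlated. One known consequence is
discussed under "Limitations".

### Seeding

One master seed controls everything. Stage names (CRC-32-hashed) and
integer indices form `numpy.random.SeedSequence` spawn keys, giving every
stage and every (family, noise level, replicate) cell an independent,
reproducible stream. Re-running any experiment with the same master seed
reproduces result files byte for byte.

## Genotype QC

Order-fixed pipeline matching the panel's marker-editing narrative:

1. **Call-rate filter**: markers with call-rate ≤ 0.85 removed (inclusive).
2. **Imputation**: each missing call filled with the dosage mean of the k =
   5 nearest samples (root-mean-square dosage distance over mutually
   observed markers; the normalization keeps pairs with different overlap
   comparable), rounded half away from zero and clipped to {0, 1, 2}.
   Neighbours must observe the marker; fallback is the marker mode, then
   dosage 0 with a warning for a fully missing marker. This imputer is the
   package's own documented choice; the original study cites an external
   method whose algorithm is not described.
3. **MAF filter**: markers with minor-allele frequency ≤ 0.025 removed
   (inclusive), computed after imputation.

On the default fixture this yields exactly 192 → 191 → 175 markers.
Per-sample call-rate is reported but never filtered on. QC is idempotent.

## Label noise

`flip_labels` inverts the labels of exactly `round(p·n)` (half away from
zero) distinct observations sampled uniformly without replacement — an
exact-count protocol, not per-label Bernoulli noise. At p = 0.5 with n =
123 this flips 62 labels, slightly more than half; the expected frequency
of the original minority class after flipping is f + p(1 − 2f) evaluated at
the realized fraction 62/123. Noise is injected once per replicate over the
full sample (the alternative — flipping independently within each training
partition — is available as `flip_scope="per-fold"`); validation
predictions are always scored against the original labels.

## Classifiers

All five families expose `fit(X, y)` / `decision_scores(X)` with higher
score = more positive (positive = high vigor), so AUC is comparable across
families and invariant to monotone score rescaling.

- **KNN** (native): Euclidean distances on dosages scaled to [0, 1] and
  normalized by √m, so D_E ∈ [0, 1]. Vote weights: uniform, 1 − D_E
  (clamped at 0), or 1/D_E with zero-distance neighbours treated as
  infinitely heavy (majority among exact matches). Distance ties break
  toward the lower training index; score ties at 0.5 classify positive.
  Grid: K ∈ {1, 3, 5, 7} × three weightings.
- **Ridge logistic regression** (native): logit p = μ + Σ z_j β_j with an
  ℓ2 penalty (λ/2)Σβ_j² on the marker effects only, fitted by IRLS (Newton
  with step halving) to gradient norm ≤ 1e−6 or 100 iterations
  (non-convergence warns and flags the model). λ grid: powers of ten from
  10⁻³ to 10³, most-regularized first for tie-breaking.
- **Random forest** (scikit-learn behind the contract): B trees grown to
  purity on bootstrap resamples, Gini splits over m random markers per
  node; score = fraction of trees voting positive (identical to averaged
  pure-leaf probabilities). Grid: B ∈ {1, 5, 10, 50, 100}, m ∈ {j, 2, 4}
  with j = int(log₂(#markers) + 1) = 8 for 175 markers.
- **SVM, linear and RBF kernels** (scikit-learn behind the contract):
  soft-margin SVC at KKT tolerance 1e−3; score = signed decision value.
  Grids: C ∈ {2², …, 2⁹}; γ ∈ {10⁻³, …, 10¹} (powers of ten).

Tuning-grid tie-breaks prefer the grid point listed first; grids are
ordered simplest-first (smaller K/B/C/γ, larger λ).

## Cross-validation and metrics

Each replicate draws one noise realization and one stratified 5-fold split
(123 → fold sizes 25/25/25/24/24). Stratification uses the true labels:
with only 24 negatives, plain random splits can produce validation folds
without a negative, leaving AUC undefined. Per outer fold, hyperparameters
are chosen by an inner stratified 5-fold CV of the training partition,
maximizing mean AUC against the noisy labels (the truth is unavailable at
tuning time); the inner folds are fixed per (replicate, outer fold) across
grid points. The chosen model is refitted on the whole training partition
and scored on the validation partition against the original labels.

Metrics per fold: TER = (FP+FN)/n, FNR = FN/(TP+FN), FPR = FP/(FP+TN),
TPR = 1−FNR, TNR = 1−FPR (identity-consistent definitions), and AUC in the
Mann–Whitney form with mid-ranks for ties, which equals the trapezoidal
area under the ROC curve exactly. Rates with empty denominators and AUC on
single-class folds are NaN and excluded from cell means. Cells aggregate
the per-fold records (macro averaging) with means and SDs.

## Experiments

The noise ladder sweeps 14 mislabel proportions (0, 1, 2.5, 5, 7.5, 10,
12.5, 15, 17.5, 20, 25, 30, 40, 50 %) for each family. The informative-
subset experiment ranks markers once, on clean labels, by the R² of the
single-marker regression of label on dosage (squared point-biserial
correlation; ties break to the lower marker index) and repeats the ladder
for KNN and RF on the full panel and the top-50 / top-30 subsets. Child
seeds depend only on (family, noise level, replicate), so the full-panel
subset reproduces the main ladder exactly and subset comparisons are
paired.

### Problem sizes

The default replicate count is 20 per cell (the full study design of 100
is a flag away); the maximal-noise check uses 50 replicates, and the class-
balance drift check 300 independent flip seeds. At maximal noise the tuned
hyperparameter is immaterial — the labels carry no signal — so the
50-replicate sweep of the slower families runs with documented mid-grid
single-point "grids" (KNN keeps its full grid); the decay-curve runs for
the global methods thin the LR λ grid to {10, 1, 0.1}. All such thinned
grids are explicit `ExperimentConfig.grids` entries, not hidden defaults.

## Limitations

- The frequency-contrast architecture gives the classes a very wide margin
  relative to within-class variation. Heavily regularized ridge logistic
  regression then behaves like a class-centroid discriminant, which random
  label flips attenuate but barely rotate: on this fixture LR remains far
  more noise-tolerant than on the real panel, where its accuracy decayed
  roughly linearly with the mislabel proportion. The linear SVM, whose
  hinge loss responds to individual flipped points near the margin, does
  reproduce the approximately linear decay. Robustness *orderings*
  involving LR on this fixture should therefore be read with care; they
  are a property of the synthetic architecture, not evidence about real
  data.
- Exact-count flipping at p = 0.5 inverts 62/123 > half of the labels, so
  noisy labels are slightly anti-correlated with the truth and mean AUC at
  maximal noise sits marginally below 0.5, as it did in the original
  study.
- Hyperparameters are tuned for ranking (inner-CV AUC), not thresholded
  error. On clean, separable data many λ values tie at inner AUC 1.0 for
  ridge LR and the tie-break picks the heaviest regularization, whose
  predicted probabilities all sit above 0.5 (every plant classified
  positive): LR's TER at low noise can approach the minority share even
  while its AUC is 1.0. This is a property of AUC-based tuning, not a
  defect of the fit.
- The KNN distance normalization (dosages to [0, 1], distances by √m) is an
  interpretation: the 1 − D_E weighting is only meaningful for distances in
  [0, 1] and the original description does not define the normalization.
- Whether MAF should be computed before or after imputation is ambiguous;
  this package computes it after, following the editing narrative's order.
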