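# Methods

This note documents the models, conventions and design choices behind
`paradiomics`, in the order the pipeline runs.

## 1. Synthetic phantom cohort

The generator produces, per specimen, a 3D scalar volume on a fixed
(0.075, 0.075, 1.0) mm grid with an aligned binary VOI mask, and emulates
only the *statistical* structure the downstream analyses rest on — no
optical or acoustic physics is simulated.

**Geometry.** The VOI is a single axis-aligned ellipsoid centred in the grid
(default 32 × 32 × 10 voxels), sized to a per-specimen target voxel count
with a random in-plane aspect ratio in [0.85, 1.18]. Targets that do not fit
the grid raise an error. Basal target volumes are drawn from N(550, 180²)
voxels and luminal from N(350, 80²) (floored at 64), so the basal arm is
larger on average with a wider spread — a deliberate confound for the
volume-correction stage.

**Intensity histograms.** Basal VOI voxels are i.i.d. Gamma(shape 2.0,
scale 1.5) — population skewness 2/√2 ≈ 1.41 — and luminal voxels are
zero-truncated N(5, 1²), i.e. essentially symmetric. A per-specimen
lognormal jitter (σ = 0.15) on the shape/mean parameter provides
between-specimen biological variation. The background is a dim exponential
field (scale 0.3). Intensity units are arbitrary photoacoustic amplitude.

**Wavelength contrast.** Two synthetic "chromophore" curves
ε±(λ) = 1 ± A·tanh((λ − 800)/w) with A = 0.25 and w = 60 nm are mixed by a
model-specific oxygenation fraction (basal 0.30, luminal 0.70); VOI
intensities are multiplied by the mixed factor. Both model curves equal 1 at
800 nm by construction (the isobestic anchor), the map is monotone (a
positive scalar), and the factor is available in closed form for testing.
Real haemoglobin extinction tables are intentionally not embedded: the
analysis only needs smooth model-dependent contrast with an isobestic
crossing.

**Reconstruction surrogates.** `backprojection` adds seeded white Gaussian
noise (amplitude 0.25); `model_based` applies in-plane Gaussian smoothing
followed by an affine intensity rescale (gain 0.85, offset 0.3). The
smoothing width is σ = 0.4 voxels: on an i.i.d. voxel field a wider kernel
visibly destroys histogram skewness (at σ = 0.7 the basal skewness drops by
roughly 40 %), while σ = 0.4 keeps the skewness change below ≈ 0.06 yet
halves the VOI variance — exactly the intended footprint of "first-order
statistics differ between reconstructions, histogram shape does not".

**Seeding.** All randomness flows from one cohort seed through
SHA-256-derived child seeds (`derive_seed(seed, specimen_id, …)` < 2³¹), so
cohorts are bit-reproducible and independent of iteration order.

**What the phantom does not emulate.** Spatial intensity correlation within
the VOI (voxels are i.i.d. given the specimen), necrotic cores or other
internal structure, fluence inhomogeneity, reconstruction artefacts with
spatial structure, and segmentation variability. Texture features computed
on this cohort therefore carry grey-level-quantisation and noise signal but
no biologically structured texture; conclusions about *which* texture
features discriminate real tumour models do not transfer, only the
behaviour of the selection machinery itself.

## 2. Radiomic features

93 features in six families, computed natively on the 3D VOI.

* **Quantisation** is fixed bin *count* over the VOI min–max:
  `level(x) = floor(Ng (x − min)/(max − min)) + 1`, max mapped to Ng. A
  constant VOI collapses to level 1 and sets a degeneracy flag. Adding a
  constant to all intensities leaves every level map — and hence every
  texture feature — unchanged.
* **First order** (18) uses the raw intensities; only Entropy and Uniformity
  use the Ng-level histogram. Moments are population moments (÷ n);
  Skewness = m₃/m₂^1.5; Kurtosis = m₄/m₂² without the −3 correction, so a
  Gaussian scores 3. Percentiles interpolate linearly between order
  statistics; TotalEnergy multiplies Energy by the voxel volume in mm³.
* **GLCM** (24) and **GLRLM** (16) are computed per direction over the 13
  unique Chebyshev-distance-1 offsets and feature values averaged over
  directions (feature-level averaging, not matrix merging). GLCM matrices
  are symmetrised before normalisation. Directions without any voxel pair
  are skipped from the average. MCC is obtained as the second-largest
  absolute eigenvalue of the symmetrised transition matrix
  D^{-1/2} P D^{-1/2}, mathematically identical to the usual definition but
  numerically a symmetric eigenproblem.
* **GLSZM** (16) zones and **GLDM**/**NGTDM** neighbourhoods use
  26-connectivity. GLDM uses dependence tolerance α = 0 (equal level) with
  matrix column index dependence + 1. NGTDM voxels with no in-VOI neighbour
  contribute zero to s_i but still count in n_i.
* **Anisotropy.** Offsets are unit steps in voxel-index space with no
  distance weighting: since no resampling is applied despite the
  (0.075, 0.075, 1.0) mm voxels, index-space neighbourhoods are the only
  internally consistent choice.
* **Degenerate inputs** never produce NaN: entropy/contrast-type features
  take 0, uniformity-type take 1, Correlation/MCC take 1, NGTDM Coarseness
  is capped at 10⁶ when its denominator vanishes; the affected names are
  flagged and the flag propagates to the feature table.

Every family is validated to 1e-10 against brute-force pair/run/zone/
neighbourhood enumeration oracles on random volumes up to 6 × 6 × 4 at 2, 4
and 8 grey levels.

## 3. Eta-squared sensitivity analysis

Per feature, the total sum of squares over the factorial table is
apportioned into main-effect shares η²_f = SS_f/SS_total with
SS_f = Σ_levels n_l (ȳ_l − ȳ)², and error = 1 − Σ η²_f, which lumps
interactions with residual variance. This is a descriptive decomposition:
with a fully balanced design all classical sum-of-squares types coincide,
which is why balance is a *precondition* (violations raise an error naming
the offending cells) rather than something the estimator works around.
Constant features decompose to all-zero shares with a degeneracy flag
instead of 0/0.

Standardisation fixes one factor at a level and re-decomposes over the
rest; the fixed factor's share is zero by construction.

The k-fold scheme removes seeded random specimens per model in each fold
(default: down to equal arms of 8 for a 10/11 cohort, mirroring a five-fold
removal of 2 basal and 3 luminal), re-runs the decomposition, and reports
mean, sample (n − 1) standard deviation and CoV = σ/mean per feature ×
factor. A CoV with mean share below 1e-6 is reported as undefined rather
than as an exploding ratio.

## 4. Discrimination analysis

* **Volume correction.** Features whose Spearman correlation with the VOI
  voxel count is significant (p < 0.05) are fitted with value = a·V^b by
  least squares in log–log space and replaced by the log-residuals recentred
  at the feature's grand mean; other features pass through untouched. When a
  feature takes non-positive values it is shifted so its minimum sits at 1 %
  of its range before the log — large enough to avoid log blow-ups, small
  enough not to mask the power law. The procedure sits behind a single
  interface so an alternative de-confounding rule can be swapped in.
* **Kruskal–Wallis / Benjamini–Hochberg.** Tie-corrected H with a chi-square
  p-value per feature (constant features are excluded with a log entry, not
  assigned p = 1), then step-up BH at q = 0.25 with deterministic (p, name)
  tie ordering. The liberal q reflects this stage's role as a coarse
  pre-filter, not an inferential claim.
* **Repeated-measures correlation.** Feature–feature correlation after
  removing subject means, with subject = specimen: the 108 conditions of one
  tumour are repeated measures, not independent observations. The matrix
  form is the plain correlation of subject-centred columns. df = N − k − 1
  with the usual t transform for p.
* **Single-feature scores.** Per candidate feature, the best mean accuracy
  over a random forest (100 trees), gradient-boosted trees (depth 3, 100
  estimators, learning rate 1.0) and an RBF SVM (γ = 0.05, C = 1.0,
  tol = 0.001), under specimen-grouped 5-fold cross-validation so no
  tumour's conditions straddle a train/test split.
* **Pruning.** Pairs with |r| > 0.9 are resolved greedily in descending |r|;
  the lower-scoring member is dropped, score ties broken by registry order.
  On exit no surviving pair exceeds the threshold, and the selected set is
  by construction a subset of the BH survivors.
* **Shapley ranking.** A seeded random forest (100 trees) on the selected
  features; attributions explain the predicted probability of the luminal
  class against the interventional value function
  v(S) = E_b[f(x_S, b_~S)] over a background sample. Exact coalition
  enumeration is used when the feature count is ≤ 15 *and* the implied
  prediction workload fits a 5 × 10⁶-row budget; otherwise a seeded
  permutation Monte-Carlo estimator. Both satisfy local accuracy
  (base + Σφ = f(x)) exactly by telescoping, which the tests assert to
  1e-8; at ≤ 3 features the attributions equal a full coalition-enumeration
  oracle to 1e-6.

## 5. Problem sizes and numerical conventions

The study-sized run used throughout testing and in `scripts/acceptance.py`
is 10 basal + 11 luminal specimens (balanced to 10 + 10 for the
decomposition), 9 wavelengths × 6 grey-level settings × 2 reconstructions
(2160 balanced rows), VOIs of roughly 200–900 voxels on a 32 × 32 × 10
grid, five folds, and seeded subsampling inside the discrimination stage
(600 rows for single-feature scoring; 128 attributed rows and a background
of 24 with 32 permutations for the Shapley stage). These sizes keep a full
pipeline run at a few minutes on one CPU while leaving every statistical
property measurable; they are configurable through `RunConfig`.

Tolerances: η² closure is exact to machine precision on balanced input;
texture-matrix normalisation to 1e-12; oracle equivalence to 1e-10 (the
eigenvalue-based MCC is compared between two symmetric-solver routes);
Shapley local accuracy to 1e-8.

## 6. Known limitations

* The phantom's i.i.d. voxel intensities make texture families informative
  about quantisation and noise, not about biological texture; a passing
  pipeline demonstrates correct machinery, not clinical discriminative
  power of specific texture features.
* The volume-correction rule (power-law residualisation with a Spearman
  gate) partially absorbs genuine between-model signal whenever tumour
  model and volume are confounded — as they are here by design and in the
  real setting it mimics. Features surviving it are conservative picks.
* Shape features, filtered-image features, 2D per-slice features and
  resampling are out of scope; the extractor refuses nothing but warns on
  grey-level counts outside the study set.
* Reconstruction surrogates target first-order footprints only; they do not
  model streaks, limited-view artefacts or depth-dependent fluence.
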