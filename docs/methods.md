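# Methods

## Image variants

**Laplacian of Gaussian.** The band-pass filter is the negated 2-D LoG

K(x, y) = −(1/πσ⁴) · (1 − r²/2σ²) · e^(−r²/2σ²),  r² = x² + y²,

sampled on an odd grid of half-width ⌈4σ⌉ pixels and shifted to be exactly
zero-sum, so constant regions map to zero and the response is invariant to
intensity offsets. It is applied slice-wise in the axial plane with
symmetric boundary extension; σ is in pixels. σ = 0 denotes no filtration
(the original image). Default σ grid: 1.0 (fine), 1.5 and 2.0 (medium),
2.5 (coarse texture). Applying the filter in 2-D per slice rather than in
3-D is a deliberate choice for anisotropic MR stacks (4 mm slices vs
sub-millimetre in-plane resolution); a 3-D LoG at these σ would mix slices
at very different physical scales.

**Wavelets.** Each volume is decomposed once, undecimated, into the 8
subbands LLL…HHH (low/high per axis, x then y then z) using the coif1
analysis filters with symmetric extension. Undecimated filtering keeps
every subband at the input shape and makes the transform shift-consistent.
The implementation is an explicit separable filter bank (not `pywt.swtn`,
which imposes periodization and even-length axes). With circular extension
the orthonormal bank is a tight frame — subband energies sum to 8× the
input energy — which the test suite verifies as the completeness /
invertibility property.

**Variant indexing.** Per sequence: variant 1 = original, 2–5 = LoG by
ascending σ, 6–13 = wavelet subbands in lexicographic order with L < H.
The mapping is a pure function of the catalog, never of the data.

## Feature catalog

The catalog fixes 485 features per sequence, 970 per patient:

| block | count | computed on |
|---|---|---|
| shape | 11 | mask only (variant 1) |
| first-order | 19 | original image |
| GLCM | 24 × 13 variants | discretized ROI |
| GLRLM | 11 × 13 variants | discretized ROI |

Keys follow `{sequence}_{variant}_{family}_{name}`. Choices behind the
numbers:

- **Discretization**: 32 equal-width bins between the in-mask minimum and
  maximum (configurable); a constant region maps wholly to level 1.
- **Texture aggregation**: co-occurrences (distance 1) and runs are
  accumulated over the 13 unique 3-D directions and merged into a single
  matrix per variant before normalization, which is deterministic and
  avoids per-direction averaging conventions. GLCM matrices are
  symmetrized; run percentage is normalized by voxels × directions so it
  stays in (0, 1].
- **GLCM set** (24): autocorrelation, cluster prominence/shade/tendency,
  contrast, correlation, difference average/entropy/variance,
  dissimilarity, energy, entropy, homogeneity1 = Σp/(1+|i−j|),
  homogeneity2, IDMN, IDN, IMC1, IMC2, inverse variance = Σ_{i≠j}p/(i−j)²,
  maximum probability, sum average/entropy/variance, variance. Entropies
  are base 2. Degenerate marginals (σx = 0 or zero marginal entropy) give
  correlation = 1 and IMC1 = IMC2 = 0 by convention.
- **GLRLM set** (11): SRE, LRE, GLN, RLN, RP, LGLRE, HGLRE,
  SRLGLE = [Σ r(i,j)/(i²j²)]/Nr, SRHGLE, LRLGLE, LRHGLE.
- **First-order** (19): mean, median, min, max, range, variance (population),
  std, skewness, kurtosis (Pearson, zero for constant regions), energy,
  entropy and uniformity on a 32-bin histogram, RMS, mean absolute
  deviation, 10th/90th percentiles, IQR, robust MAD (within [p10, p90]),
  total energy (voxel volume × energy).
- **Shape** (11): volume (voxel count × voxel volume), marching-cubes
  surface area, surface/volume ratio, sphericity, compactness 1 and 2,
  spherical disproportion, maximum 3-D diameter, and the three PCA axis
  lengths 4√λ in physical coordinates.

First-order features are computed on the original variant only; filtered
information enters through the texture families. This is what makes the
printed totals (11 + 19 + 35×13 = 485) come out exactly.

**Boundary effect.** Filtered variants are computed from the whole volume,
so tissue just outside the ROI contributes to band-pass responses at the
ROI boundary — standard behavior for radiomics pipelines. Statistics
(discretization, matrices, histograms) use in-mask voxels only, and
co-occurrence pairs / runs never bridge out-of-mask gaps.

## Normalization and the volume audit

Features are z-scored with the population convention (ddof = 0); the
statistics are estimated on the discovery set and applied frozen to the
validation set. Zero-variance features are flagged and withheld from model
selection but kept in the table. The feature–tumor-volume audit computes
Spearman ρ per feature and buckets |ρ| at breakpoints 0.26 / 0.50 / 0.70 /
0.90 into little-if-any / low / moderate / high / very-high correlation.

## Signature

Selection is an L1-penalized Cox partial-likelihood fit over the
coordinate-descent regularization path. The penalty is chosen by k-fold
(default 10, seeded) cross-validation of the held-out log partial
likelihood computed as ll(all) − ll(train) (the Verweij–van Houwelingen
construction), at the maximizing penalty (`min` rule) or the strongest
penalty within one standard error (`1se`). A Cox model has no native
intercept; the Rad-score intercept is a centering constant — minus the mean
linear predictor of the fitting set — so fitted Rad-scores average zero
there, and the risk cutoff is the fitting-set median, frozen for
validation. The published NPC model (five features, printed coefficients,
intercept −7.995, cutoff −6.863, ≥ cutoff ⇒ high risk) ships as a constant
and is used verbatim.

## Survival analysis

Cox models use the Efron tie approximation with Wald 95% CIs. Model 1
contains age, sex, overall stage, hemoglobin and platelets; model 2 adds
the Rad-score — continuous by default, dichotomized at the cutoff by flag.
Backward AIC step-down elimination is available but off by default so the
model 1 / model 2 tables stay directly comparable. Discovery and validation
models are refit separately (the signature and cutoff, not the Cox
coefficients, are what is frozen). Kaplan–Meier estimation and the k-sample
log-rank test are the lifelines implementations; the stratified analysis
reports, per clinical subgroup, the across-bin log-rank p and the
within-bin low-vs-high Rad-score log-rank p in one long-format table.

## Synthetic cohort generator

What it emulates, per patient:

- **Tumor geometry**: an ellipsoid with per-patient jittered radii
  (~30% of each grid dimension), strictly inside the grid; default grid
  32×32×16 voxels at 0.9×0.9×4.0 mm, mimicking anisotropic axial MR stacks
  at reduced matrix size.
- **Intratumoral texture**: a unit-variance Gaussian random field whose
  in-plane correlation length shrinks (2.2 → 0.4 voxels) and whose
  white-noise share and contrast grow monotonically with a scalar latent
  heterogeneity h ∈ [0, 1]; a patient-specific coarse component (σ = 3
  voxels, random weight) and mild random anisotropy give features across
  filter variants idiosyncratic variance. Both sequences share h and the
  mask but have independent field realizations.
- **Clinical covariates** (independent of hazard by default, matching the
  null clinical findings the design mirrors): age ~ N(43, 9.5²) years
  clipped to [18, 75], 75% male, 35% stage IV, hemoglobin ~ N(155, 20²)
  g/L, platelets ~ N(170, 45²) ×10⁹/L.
- **Survival**: exponential event times from hazard h₀·exp(lp) with
  h₀ = 0.015/month, censored by uniform dropout on [0.1, 1]× an 89-month
  window (~50% events, median follow-up ≈ 45 months). The linear predictor
  is lp = Σ_k β_k z_k over the *planted* features: texture features
  extracted from the generated images and z-scored across the cohort, with
  per-SD log-hazard effects β (default magnitude 1).
- **Split**: seeded permutation, discovery count rounded half-up
  (70/30 at n = 100).

**Planted-set identifiability.** The default planted set
(`T2w_7_GLCM_correlation`, `CET1w_12_GLCM_cluster_shade`,
`T2w_1_firstorder_kurtosis`, `CET1w_11_GLRLM_gln`,
`CET1w_2_GLCM_inverse_variance`; effects +1, +1, +1, +1, −1 per SD) was
chosen for bounded redundancy: each member's maximum |ρ| with any other
catalog feature is ≤ 0.81 and mutual |ρ| ≤ 0.33 under the reference
generator, and one member is strongly heterogeneity-linked (ρ ≈ −0.57 with
h) so hazard remains tied to the latent. This matters because the catalog
contains near-duplicate feature pairs (e.g. GLCM inverse variance vs
homogeneity2, ρ ≈ 0.999 on smooth fields; GLRLM SRLGLE vs LGLRE,
ρ ≈ 0.998): no sparse selector can distinguish a feature from such a twin
at n = 70, so a recovery experiment planted on them would be ill-posed —
the lasso support-recovery (irrepresentable) condition fails. Even with the
low-redundancy set, exact 5-of-5 recovery is a property of the reference
conditions and seed; at other seeds the cross-validated lasso occasionally
trades one planted feature for a correlated surrogate, which is the
expected behavior of support recovery at this sample size.

**What the generator does not emulate**: MRI physics (bias fields, coil
artifacts, partial-volume effects), non-ellipsoidal or infiltrative tumor
shapes, inter-sequence intensity relationships, EBV-DNA biology, and any
dependence of clinical covariates on outcome. Passing tests therefore
demonstrate the correctness and statistical calibration of the pipeline
machinery, not clinical performance on real NPC data.

## Numerical conventions and degenerate inputs

- All randomness descends from one integer seed through
  `numpy.random.SeedSequence.spawn`; every output is a pure function of
  (config, seed).
- Risk assignment uses ≥ cutoff ⇒ high (ties go high).
- Discretizing a constant ROI yields level 1 everywhere; its GLCM is a
  point mass with correlation 1 by convention.
- Zero-variance Cox covariates are dropped with a warning; fewer rows than
  CV folds reduces the fold count with a warning; a model with no events
  is an error.
- Linear predictors are clipped to ±30 before exponentiation in the
  survival simulator; observed times are floored at 10⁻⁹ months so the
  censor-window → 0 boundary stays representable.

## Problem sizes

The shipped test suite runs the reference cohort at the study design
(n = 100 patients, 70/30 split) on the default 32×32×16 grid, end-to-end
smoke runs at n = 40, and estimator-calibration simulations at n = 1000
(Cox) and 1000 replicates (log-rank type-I error); these sizes were chosen
so the whole suite completes in a few minutes on one CPU while keeping
every statistical check adequately powered.

## Known limitations

- The feature definitions follow the documented catalog, not a certified
  IBSI implementation; 2-D single-slice feature modes are out of scope.
- The LoG is 2-D slice-wise by design; a 3-D option is not provided.
- The wavelet basis (coif1), discretization depth (32), and texture
  aggregation (merged matrices, distance 1) are fixed conventions exposed
  as parameters, not fitted choices.
- Cox model 2 treats the Rad-score as continuous by default although the
  risk groups are defined by a median split; both modes are exposed
  because study reports are ambiguous on this point.
- Interaction terms between features are deliberately not considered.
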