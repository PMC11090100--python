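# Methods

## Model and procedure

The quantity of interest is the group difference in seed-to-voxel structural
covariance. For each of the 18 amygdala subregion seeds, every voxel `v` is
modelled across subjects as

    GMV_v = β1·SCZ + β2·HC + β3·(VolS×SCZ) + β4·(VolS×HC) + β_covs·Covs

with `SCZ`/`HC` group indicators, `VolS` the seed volume, and covariates
age, sex (M=0, F=1) and total intracranial volume, mean-centered. Centering
makes `β1, β2` group intercepts at covariate means and improves
conditioning; it does not change the `β3 − β4` contrast or its t statistic.
Fitting is ordinary least squares via one QR factorization shared across
voxels; `t = c'β / √(σ̂²·c'(X'X)⁻¹c)` with `c = [0,0,1,−1,0,…]` and
`σ̂² = RSS/(n − p)`. Testing is two-sided throughout: the direction of a
covariance disruption is not assumed a priori.

### Harmonization

Site effects are removed before statistics with parametric empirical-Bayes
ComBat: per-feature standardization on the full-cohort fit (batch indicators
plus the biological design: group, age, sex, TIV), normal prior on per-batch
location `γ`, inverse-gamma prior on scale `δ²`, hyperparameters by method
of moments across features, posteriors by iterated conditional means
(convergence `max|Δ| < 1e-6`, cap 1000 iterations). Two conventions are
deliberate:

- Per-batch scale estimates use the population divisor `n_i`, consistent
  with the divisor-`n` pooled variance. A single batch then standardizes to
  exactly (0, 1), harmonization of single-site data is an exact identity,
  and the non-EB variant reproduces the closed-form standardization
  exactly. The difference from the common ddof=1 convention is `O(1/n_i)`.
- Both the voxel matrix and the seed-volume table are harmonized by default
  (the seeds enter the design of every downstream model, so leaving site
  effects in them would leak batch structure into the interaction); a flag
  disables seed harmonization.

Only the parametric variant is implemented; non-parametric, reference-batch
and covariance-preserving variants are out of scope.

### Permutation TFCE–FWE inference

Significance is assessed non-parametrically. The default scheme is
Freedman–Lane for the interaction contrast: fit the reduced common-slope
model (group intercepts + VolS + covariates), permute its residuals, add
back the reduced fit, refit the full model. This keeps nuisance structure
(including a genuine but group-equal covariance slope) in place under the
null. Whole-row group-label exchange is available as an alternative scheme.

TFCE uses the canonical exponents E=0.5, H=2, 6-connectivity and 100
integration steps with `dh = map-maximum / 100` (an explicit `dh` may be
given instead). Signed maps are enhanced in both directions and each
permutation contributes the maximum over signs and voxels, controlling FWE
for either direction jointly. The implementation processes voxels in
descending order with an incremental union-find (numba-compiled), which
reproduces per-threshold connected-component labelling to round-off while
being fast enough for thousands of permutations per seed. The FWE p value
uses the `(1 + count)/(n_perm + 1)` convention, the observed statistic
playing the role of permutation zero, so the smallest attainable p is
`1/(n_perm + 1)`; the production default is 5000 permutations, scaled down
in simulation studies (see problem sizes below).

Because one contrast is tested per subregion, the per-seed threshold is
Bonferroni-adjusted by the Li–Ji effective number of independent tests,
computed from the eigenvalues of the Pearson correlation matrix of the 18
harmonized seed volumes: `Meff = Σ [1{|λ|≥1} + frac(|λ|)]`, threshold
`α/Meff`. Eigenvalues within round-off of an integer are snapped before the
fractional part is taken (an identity matrix must give exactly M).
Significance decisions are strict inequalities (`p < α/Meff`).

### Target ROIs, fingerprints, validation

Per-seed significance masks are OR-merged into a union mask and intersected
with an integer-labelled parcellation. A region becomes a target ROI when
its overlapping ratio (intersection / region volume) exceeds 15% AND its
intersection volume exceeds a configurable floor (default 1 mm³; the floor
is kept configurable because a 1 mm³ criterion is vacuous at smoothed-VBM
resolutions and may reflect a transcription slip in its source). Mean GMV is
extracted per subject over the full atlas region by default, with an
intersection-only option.

Each seed×ROI cell refits the interaction model at ROI level; the
standardized effect size is Hedges' adjusted
`g* = t·√(1/n₁ + 1/n₂)·J`, `J = 1 − 3/(4·df − 1)`, with forest-plot
standard error `SE² = (1/n₁ + 1/n₂) + g*²/(2·df)`. Per-center validation
refits within each center, requiring at least 3 subjects per group per
center (df > 0 with covariates); smaller centers are excluded with a logged
warning. Sex-stratified cells are fitted within each sex (age and TIV as
covariates); the formal inter-sex comparison is the pooled
group×sex×volume factorial contrast `((β3−β4)_M − (β3−β4)_F)`, reported
uncorrected. A pooled interaction test was chosen over comparing two
independent fits because it is an actual hypothesis test of the sex
difference rather than a qualitative contrast of two results.

Subregion-volume comparisons use `volume ~ group + age + TIV` within a sex
subset and `volume ~ group·sex + age + TIV` for the inter-sex interaction.

### Clinical association

Group-level covariance has no per-subject value, so the package defines a
documented proxy: the product of z-scores (population normalization within
the analyzed patients) of seed volume and ROI mean GMV, optionally after
residualizing both on age, sex and TIV. Its sample mean equals the Pearson
correlation of the two inputs, and it is invariant to affine rescaling of
either input. Proxies are rank-correlated (tie-corrected Spearman, two-sided
p by the t approximation) against clinical variables in patients only,
pairwise-complete, reported uncorrected with an optional FDR column.

## The synthetic generator

The generator emulates the *outputs* of a VBM + subfield-segmentation
pipeline — never raw images, segmentation or registration. Per subject `j`
of site `i`, voxel `v`:

    GMV_jv = α_v + a·age_j + s·sex_j + t·TIV_j + Σ_seeds β_{g(j),seed,v}·Vol_seed,j
             + γ_i + δ_i·ε_jv

Defaults (chosen once for realism/testability; magnitudes of covariance
disruptions are not published anywhere, so planted effect sizes are chosen
for testability): baseline α = 4 mm³/voxel on a 16³ grid of 2 mm voxels
with an interior-box mask; age effect −0.012 mm³/yr; sex effect
0.10 mm³ (F−M); TIV effect 1.5·10⁻⁶ per mm³; noise σ = 0.4; additive site
offsets γ ~ N(0, 0.5); scale factors δ log-normal (σ_log = 0.2); a
group-equal coupling of every voxel to whole-amygdala volume
(0.001 mm³/mm³) so each subregion seed sees a nonzero nuisance slope
through inter-volume correlation. Group slope differences exist only on
planted voxel clusters recorded in the ground-truth object. Gaussian
smoothing is off by default and available at a reduced kernel (it
correlates noise, which the calibration experiments deliberately study
without).

Subregion volumes are multivariate normal at FreeSurfer-typical means
(La 700, Ba 450, AB 255, AAA 60, Ce 55, Me 30, Co 30, CAT 190, PL 55 mm³
per hemisphere, CV 0.12) with exchangeable correlation 0.5 and a default
5% patient deficit in every subregion; whole-amygdala volumes are the
hemisphere sums plus noise (segmentations need not tile). Cohorts draw ages
from a truncated normal on [16, 70] and TIV with sex-dependent means; by
default each site's controls are matched to its patients (ages jittered,
sexes permuted), so per-site sex tables are exactly balanced. Clinical
scores are independent of imaging by default; a monotone link of chosen
Spearman strength can be planted (Gaussian-copula reassignment preserving
the marginal exactly).

What passing tests on these data do **not** show: robustness to
registration error, non-Gaussian site effects, scanner-specific spatial
autocorrelation, or realistic anatomical covariance topography. The
generator's location/scale site model is exactly the model ComBat assumes,
so harmonization results on it are a best case.

## Numerical choices and degenerate inputs

- GMV values are floored at zero (physical non-negativity); planted slopes
  must be small enough relative to the intercept that the floor is inactive,
  else recovery is intentionally distorted.
- The GLM raises on rank-deficient designs (QR diagonal tolerance 1e-10
  relative), on non-finite data, and on numerically zero residual variance
  (RSS below 1e-24 of the data's sum of squares).
- TFCE absorbs round-off when the map maximum is an exact multiple of `dh`
  (tolerance 1e-9·dh), so analytic step-ladder values are reproduced
  exactly.
- The random parcellation assigns mask voxels to their nearest randomly
  chosen centroids (first minimum on ties), guaranteeing a deterministic
  exact partition with non-empty regions.
- All generators and the permutation engine take explicit integer seeds;
  identical seeds are bit-reproducible.

## Validation experiments and problem sizes

`amycov.experiments` regenerates data with known truth and measures
operating characteristics; the acceptance runner and test suite reuse them.
Sizes were fixed in advance as the smallest that make the checks sharp:
familywise error of the permutation TFCE test from 200 replicate null
datasets (60 subjects, 16³ grid) × 500 permutations; planted 27-voxel
cluster recovery at n = 200/group with 500 permutations against the
Meff-adjusted threshold; ComBat recovery of a planted (+2.0, ×2.0) batch
effect over 2000 features; ROI-level null calibrations from 200–600
replicates. The acceptance script runs a 100×300 version of the familywise
calibration.

## Known limitations

- Only the `β3 − β4` contrast is supported by the Freedman–Lane engine;
  arbitrary contrasts would need a generalized reduced-model construction.
- ComBat assumes location/scale site effects; site-by-covariate
  interactions are neither modelled nor removed.
- The per-subject covariance proxy is one defensible choice among several;
  subject-level covariance is not a standardized quantity, so clinical
  correlations are comparable only within a fixed proxy definition.
- No meta-analytic (random-effects) pooling across centers; per-center
  effects are displayed, not combined.
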