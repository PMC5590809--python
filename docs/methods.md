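# Methods

`radiomod` reimplements a radiogenomic inference chain for solid-tumor
imaging cohorts: a fixed bank of quantitative image descriptors is extracted
from 3D tumor volumes, each descriptor is scored against genome-wide
expression by weighted-rank gene-set enrichment, the resulting
feature-by-pathway score matrix is biclustered into association modules that
are validated on an independent cohort by permutation, modules are related
to survival, stage and histology through a two-cohort meta-analysis, and
radiomic predictors of pathway activation and prognostic signatures are
built on top. A synthetic cohort generator with planted, known structure
drives all end-to-end verification.

## Image preprocessing

Volumes are voxel-indexed `(z, y, x)`, 0-based; `spacing_mm` follows the
same order. Intensities are resampled trilinearly to an isotropic grid
(default 1 × 1 × 1 mm, the standard normalization for CT radiomics); masks
are interpolated linearly and re-thresholded at 0.5 so they stay binary.
Gray levels for the texture matrices come from fixed-width binning,
`level = floor((I − min_masked) / w) + 1` with `w = 25` intensity units by
default — the fixed-bin-width convention of CT radiomics, with the minimum
taken over masked voxels only. Both `w` and the target spacing are
configuration fields and enter the provenance hash.

## The feature bank (636 features, 440-feature prior subset)

| group | contents | count |
|---|---|---|
| first order | 14 intensity statistics | 14 |
| shape | 8 size/shape descriptors | 8 |
| GLCM | 23 co-occurrence features, 13 directions averaged | 23 |
| RLGL | 11 run-length features, 13 directions averaged | 11 |
| GLSZM | 14 size-zone features, direction-free | 14 |
| wavelet | 8 stationary sub-bands × (14 + 23 + 11) | 384 |
| LoG | 13 scales (1.0–7.0 mm by 0.5) × 14 first-order | 182 |

The bank enumeration is a pinned configuration contract: the published
feature set this bank extends counts 440 = 14 + 8 + 34 texture +
8 × (14 + 34) wavelet features, which fixes GLCM + RLGL at 34 — hence the
23-feature GLCM set (the classic 22 plus Haralick's difference variance)
next to the standard 11-feature run set. The 196 added features split into
a 14-feature size-zone set (the standard 11 emphases/nonuniformities plus
gray-level variance, zone-size variance and zone-size entropy) computed on
the unfiltered image only, and Laplacian-of-Gaussian first-order statistics
at 13 physical scales. A coarser 7-scale LoG grid cannot reach the 196-count
with any standard size-zone set, so the half-millimeter grid is the bank's
own choice; it spans the same 1–7 mm range of CT texture scales.

Conventions that matter:

- **Shape** uses the voxel-face surface convention (sum of exposed voxel
  faces, in mm²). This overestimates smooth surfaces by up to ~1.5×, so
  digital spheres plateau near sphericity 0.67 rather than 1; the
  isoperimetric bound "sphericity ≤ 1" still holds, and the convention makes
  every value exactly reproducible by enumeration. Maximum 3D diameter is
  the largest distance between masked voxel centers (0 for a single voxel),
  computed on boundary voxels.
- **Texture** matrices use distance-1 adjacency on the voxel grid over the
  13 unique 3D directions, symmetrized and normalized per direction, with
  features averaged over directions (not concatenated). Size zones are
  26-connected components of constant gray level. Two conservation
  identities are exact and tested: run lengths and zone sizes each sum to
  the masked voxel count.
- **Wavelet** features use a one-level 3D stationary (undecimated)
  decomposition with Coiflet-1, the basis of the prior feature set; odd axes
  are edge-padded to even length and cropped back. First-order, GLCM and
  RLGL are recomputed per sub-band within the original mask; sub-band maps
  are re-discretized with the same bin width relative to their own masked
  minimum.
- **LoG** responses are computed at physical scales (`sigma_mm` divided by
  the per-axis spacing), then summarized by the 14 first-order statistics.
- **Degenerate statistics** (correlation of a single-level image, IMC of a
  constant sub-band) emit 0 with a logged warning instead of failing,
  because constant sub-bands are routine on real masks.

## Enrichment scoring

For one radiomic feature, every gene is scored `s_g = rho_g · (−log10 p_g)`
where `rho` is Spearman's correlation across patients and `p` its two-sided
significance (exact permutation enumeration for n ≤ 9 patients, t
approximation otherwise, floored at 1e-300). The descending-sorted list
(ties broken by gene id) feeds the weighted Kolmogorov–Smirnov running sum:
hits advance by `|s|^w / Σ|s|^w` (default weight w = 1), misses retreat by
`1/(N − N_hit)`; the enrichment score ES is the signed extreme deviation
(a ± tie of the extreme resolves positive). Because the extremes occur
adjacent to hit positions, ES is evaluated from the hit positions in
O(m log m) rather than O(N); a full running-sum oracle verifies equality.

The null is gene-label permutation — random sets of the same size — which
depends only on the ranking and the set size, so equal-size sets share one
null family. NES divides ES by the mean same-sign null magnitude; the
p-value is the plus-one same-sign tail, which is positive and
super-uniform (verified by a KS calibration test). Benjamini–Hochberg runs
within the collection. Gene sets are intersected with the measured universe
before the inclusive 15–500 size filter.

Per-patient pathway scores use a single-sample rank statistic: genes are
ordered by expression within the patient (ties by gene id) and the same
signed max-deviation running sum is evaluated with linear descending rank
weights. This is an approximation of the kernel-density variant used by the
GSVA package — it has no bandwidth parameters, depends only on
within-patient ranks (hence is invariant under monotone transforms of a
profile), and agrees in sign semantics, which is all downstream consumers
use.

## Module discovery and validation

The feature × pathway NES matrix is biclustered with the Iterative
Signature Algorithm: rows and columns are z-scored; from sparse random row
seeds, column scores (means of row-standardized values over the current
rows) are thresholded at `t_col` SDs of the score vector, row scores
symmetrically at `t_row`, iterating to a fixed point over the liberal
threshold grid {1.5, 2.0, 2.5}². Convergence is the exact membership fixed
point or a >0.99 correlation between successive score vectors (the
criterion used by the reference implementation; exact-only convergence
discards slowly oscillating candidates). Non-converged seeds are dropped;
default 100 seeds per grid cell, configurable.

Candidates are pruned greedily: visited in order of ISA block strength (the
bilinear form of the converged score vectors on the z-scored matrix), a
candidate is dropped if the Pearson correlation of its binary membership
vector with a retained one exceeds 0.3. Block strength, not the coherence
statistic, decides precedence because the singleton-side convention below
makes coherence incomparable across module shapes (a 1 × m fragment would
always outrank the full block and then delete it as "redundant").

Module coherence is `r = mean(C_X) + mean(C_Y)`: the mean pairwise Spearman
correlation among the module's feature columns at patient level, plus the
same among its per-patient pathway score columns. Patient-level data (not
the NES matrix) is used so the identical statistic transfers to an
independent validation cohort. The mean over an empty pair set is defined
as 1, so one-sided modules remain scorable. Validation draws random modules
of identical dimensions from the validation cohort's columns without
replacement (default N = 1000) and reports the plus-one p; BH FDR runs over
the pruned candidate family. A standardized-rank identity
(`Σ_{i≠j} rho_ij = ‖Σ z_i‖²/n − k`) makes each null draw O(nk).

Module size is `n/N + m/M` against the bank and collection totals; module
overlap is the Jaccard index of feature sets after collapsing wavelet-band
and LoG-scale prefixes to base feature names, so the same statistic under
different transforms counts as shared.

### Operating characteristics at desk scale

The verification suite measures the full discovery chain on planted
two-cohort designs of 150 patients × 50 features × 500 genes. At this
scale the NES statistic saturates: the ranking weights span orders of
magnitude, so the running sum of any random 15-gene set is dominated by its
single largest weight (null |ES| floor ≈ 0.5), and a planted block of k
sets occupies 3k% of a 500-gene universe, so a large share of permuted sets
contain a planted gene and score near the observed ES. Planted cells
therefore reach NES ≈ 1.5 against a noise spread of ≈ 1.05 — detectable by
the permutation p-value (consistently ≈ 0.001 for planted sets) but near
the resolution limit of threshold-based biclustering. The measured
planted-module recovery rate of the full chain under these conditions is
reported as-is by the verification suite and the reproduction script; the
specificity guarantee (zero validated modules on null cohorts in ≥ 95% of
seeds) holds. In the regime the method is designed for — hundreds of
features, hundreds of pathways, a ~20k-gene universe, block densities below
~6% — the same chain recovers strong planted blocks reliably, which the
suite demonstrates component-wise (direct planted-matrix biclustering,
coherence separation, null calibration).

## Clinical associations

Harrell's concordance index runs over comparable pairs (the shorter time
carries an event; risk ties count ½) with a binomial-type standard error
`sqrt(C(1−C)/n_pairs)`. A module's survival statistic is the mean of
|CI − 0.5| over its features — direction-free, since features of one module
may be prognostic in opposite directions. Stage and histology use the mean
Kruskal–Wallis H (ties-corrected; 0 when all values tie). Permutation nulls
redraw random feature sets of equal size from the full table (an
outcome-permutation null would also be defensible; the feature-set null
mirrors the module-validation null). Cohorts combine by weighted Fisher-Z:
`z_i = Φ⁻¹(1 − p_i)`, `z = (n₁z₁ + n₂z₂)/√(n₁² + n₂²)`, one-sided; boundary
p-values are clamped with a warning. Stage groups are {I, II, III, other}
(late stages binned into "other") and histology
{adenocarcinoma, squamous, other}.

## Prediction and signatures

Pathway activation is the sign of the per-patient enrichment score (zero
counts as inactive, logged). Univariate logistic predictors are fitted per
(feature, pathway) pair by near-unpenalized maximum likelihood; perfectly
separated data falls back to a mild ridge so slopes stay finite. AUC is the
normalized Mann–Whitney U with tie halves; significance is Noether's
large-sample normal test against AUC = 0.5 (null variance
`(n₀+n₁+1)/(12 n₀n₁)`), replaced by an exact label-permutation test when
`n₀·n₁ < 50`. Each module's strongest predictor by training AUC (ties by
feature id) is evaluated on the validation cohort.

Prognostic signatures: mRMR ranks features greedily by rank correlation
with the martingale residual of an intercept-only Nelson–Aalen model
(relevance) minus the mean absolute rank correlation with already-selected
features (redundancy); constant columns are excluded with a warning.
Incremental Cox models of sizes 1..k (k = 15 by default) are scored by mean
held-out concordance over repeated random 70/30 splits (N = 1000 by
default, reducible; splits are unstratified), the best size is refit on the
full training cohort with a small ridge penalty (0.01) for stability, and
validated by concordance on the independent cohort. Cox-level fusion takes
scalar clinical / gene / radiomic risk scores per patient, fits a
proportional-hazards model per component subset on the training cohort and
reports each subset's validation concordance; model comparisons permute the
distinguishing component across patients and refit (plus-one p).

## The synthetic cohort generator

A Gaussian copula with latent factors. Planted links group into connected
components of the (feature, set) bipartite graph; each component has one
factor on which linked features load √s̄ and member genes ±√(s̄·|s|)/√s̄, so
gene–feature correlation ≈ the requested strength and the features of one
planted module are mutually correlated at ≈ s̄ (required for the coherence
statistic to see the module). On top, a small number of background factors
(default 5) carry shared biology: every feature and every unlinked gene
loads moderately on one random factor (genes U(0.15, 0.45), features
U(0.3, 0.6), random signs), producing block-correlated feature tables and a
continuum of background gene–feature correlations mostly below |rho| ≈ 0.3,
as real cohorts show. An iid background would make every planted gene a
lone extreme outlier of the enrichment ranking, a geometry real expression
data never produces. Background assignments are redrawn per cohort seed, so
background structure does not reproduce across cohorts — only planted
structure validates.

Survival is an exponential proportional-hazards draw on the standardized
linked feature (baseline median 24 months); the upper bound of the uniform
censoring window is solved by bisection against the drawn event times so
the realized censoring fraction matches the requested rate (±0.05 at
n = 500, tested). Stage and histology are categorical mixtures with
realistic early-stage-heavy proportions. Phantom volumes (spheres,
ellipsoids, cubes, smoothed-noise blobs with constant / Gaussian /
checkerboard / gradient textures) are bit-reproducible per seed, with
background 0 outside the single-connected-component mask.

What the generator does not emulate: scanner physics and acquisition
variability, spatial correlation of image noise, non-proportional hazards,
informative censoring, and realistic pathway-database redundancy
(gene sets are disjoint by default). Passing tests therefore demonstrate
the statistical machinery, not robustness to real-world imaging artifacts.

## Verification scales

The test suite runs the module-recovery study at 50 planted and 20 null
seeds and the signature study at 25 seeds; the reproduction script uses 12
planted / 10 null module seeds and 10 signature seeds with 10 fusion
replicates, which keeps a full run in a few minutes while leaving rates
accurate to about one part in ten. Permutation depths default to 300
(enrichment null), 1000 (module validation), and 30 CV splits in the
signature study; these sizes are the package's verification choices and are
all configurable upward.
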