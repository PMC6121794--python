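# Methods

This note documents the models and procedures `craterlakes` implements,
the defaults it ships, the synthetic data it validates itself on, and the
numerical and design choices that were genuinely open.

## Generalized Procrustes analysis

Superimposition is the partial-Procrustes variant standard in geometric
morphometrics (as in MorphoJ and geomorph): each configuration is centred,
scaled to unit centroid size (CS = √Σᵢ‖xᵢ − x̄‖²), and rotated by the SVD
solution — reflections disallowed by forcing the rotation determinant
positive, since biological landmark schemes are chirally consistent — to a
consensus that is re-estimated (centred, unit CS) each iteration until it
moves by less than `tol` (default 1e-8, max 100 iterations). The summed
squared residual around the consensus is non-increasing across iterations
and is recorded for inspection. Orientation of the solution is fixed only
up to the initial reference (the first configuration); all reported
statistics are rotation-invariant, and tests that compare planted vectors
against estimates first rotate estimates into the base frame.

No projection into tangent space is applied before computing distances:
at the shape distances relevant here (Procrustes distances ≲ 0.1) the
difference is far below the noise level. A flag is not provided because no
downstream quantity in the package would change at reportable precision.

## Allometry correction

Size effects are removed by a multivariate **pooled within-group**
regression of the superimposed coordinates on log10 centroid size: one
common slope vector **b** estimated after centring predictor and
coordinates within each group (group-specific intercepts), then

corrected = observed − **b**·(log₁₀CS − mean log₁₀CS).

Subtracting the grand-mean-anchored allometric expectation (rather than
returning raw residuals) preserves group mean differences, which is what
the downstream distances and divergence vectors consume. log10 is the
default size predictor (a raw-CS option exists) because shape–size
relations in fish body form are closer to linear on a log scale and this
matches common practice in the tools this analysis chain emulates. The
pooling groups default to the finest labels available (lake × species);
per-lake pooling is a parameter. If no within-group size variation exists
the slope is inestimable; the correction then degrades gracefully to the
identity with a warning rather than an error, since a zero-size-range
dataset is still perfectly analysable shape data.

## Group-level shape statistics

- **Procrustes distance**: Euclidean norm between group mean coordinate
  vectors on the single global superimposition.
- **Mahalanobis distance**: √(δᵀW⁻δ) with W the pooled within-group
  covariance over *all* groups. W is rank-deficient for superimposed 2D
  landmarks (4 dimensions lost to centring/scaling/rotation), so W⁻ is a
  pseudo-inverse restricted to the top r = min(n − g, requested rank)
  eigen-dimensions with eigenvalues above 1e-10 × λmax; the relative
  tolerance removes the superimposition's null directions automatically
  and keeps the computation well-defined for generic (non-landmark) toy
  data.
- **Within-lake shape variance** deliberately uses a *separate* per-lake
  superimposition (plus within-lake allometry correction): the statistic
  is then independent of which other lakes happen to be in the dataset.
  It is the mean squared Euclidean deviation of specimens from the lake
  consensus.
- **CV_ei**: per specimen the elongation index EI = d(SL pair)/d(BH pair)
  from raw coordinates (the ratio cancels photographic scale); the lake
  value is 100·sd(EI)/mean(EI) with the sample (n−1) standard deviation.
  Default landmark pairs (0, 6) for standard length and (3, 9) for body
  height match the packaged 12-landmark scheme (snout tip → mid caudal
  peduncle; dorsal → ventral extreme) and are parameters.
- **PCA / between-group PCA**: eigendecomposition of the coordinate
  covariance; bgPCA decomposes the covariance of the g equally weighted
  group means and projects individuals onto those axes. Axis signs are
  fixed by making each axis's largest-magnitude loading positive.

## Divergence vectors (dL, θ)

Each derived population is contrasted with its source by a vector of 24
two-sample t-statistics (pooled-variance by default; Welch available),
signed derived-minus-source. The *length* of a vector is the signed sum of
its t-statistics; for two pairs dL = |ΣtA − ΣtB| and
θ = arccos(Pearson corr(tA, tB)) in degrees. A signed sum can cancel
across coordinates; an alternative Euclidean-norm length is available
behind a flag but is not the default, because the signed sum is the
statistic the pairwise tables in this literature report.

**Permutation inference.** The null hypothesis is that the two pairs share
one divergence trajectory. Each of the (default 1000) permutations
reshuffles pair labels *within role*: derived specimens are exchanged
between the pairs, and source specimens likewise, sample sizes preserved;
both t-vectors are recomputed and |dL| and θ recorded. When two pairs
share a source population, the source specimens enter the pool once per
pair (a duplicated paired design); this affects only the raw-coordinate
t-statistics, never ordination scores, so duplication is harmless.
p = (count(null ≥ observed) + 1)/(n_perm + 1), one-tailed for both
statistics: the observed θ is significant when it exceeds what a shared
trajectory could produce. (A within-pair derived/source label switch was
considered and rejected: its null concentrates θ near 90° — random
high-dimensional t-vectors are nearly uncorrelated — so it could never
flag genuinely different directions.)

**Orthogonality bootstrap.** Specimens are resampled with replacement
within each of the four groups; the reported value is
2·min(frac(θ* ≥ 90°), frac(θ* < 90°)). Values ≤ 0.05 indicate the pair is
significantly more parallel (or more anti-parallel) than orthogonal.

## Population-genetic statistics

**Filtering** keeps SNPs with ≥ 6 called genotypes in every population
(≥ 3 in the designated outgroup) and then one SNP per RAD-tag locus
(first in input order); the filter is idempotent and logs per-rule drop
counts. No minor-allele-frequency filter is applied.

**Patterson's D** uses sample allele frequencies:
numerator Σ(p_W − p_X)(p_Y − p_Z), denominator
Σ(p_W + p_X − 2p_Wp_X)(p_Y + p_Z − 2p_Yp_Z); ABBA/BABA are reported as
the corresponding frequency-weighted pattern sums (their difference
equals the numerator site by site, so sign(D) = sign(BABA − ABBA)).
Missing genotypes are excluded per site per population; sites with any
population entirely missing are skipped. Standard errors come from a
delete-one block jackknife over contiguous blocks of 500 SNPs (input
order, which is genome order for a sorted VCF), weighted by block SNP
count (Busing-style; reduces to the ordinary jackknife for equal
blocks). Blocks defined by SNP count rather than genetic distance are a
documented divergence from map-based blocking: they are deterministic
and need no genetic map, at the cost of slightly optimistic SEs if LD
varies strongly along the genome. Z = D/SE, p = 2Φ(−|Z|), and the
reporting convention flags quartets at p < 0.01.

**F_ST** is the Weir–Cockerham (1984) two-population estimator, the
ratio of sums θ̂ = Σ_loci a / Σ_loci (a + b + c) with the standard
variance components computed from per-locus sample sizes, allele
frequencies and observed heterozygosities (missing genotypes reduce the
per-locus n). This is a deliberate substitution for AMOVA-based Φ-style
estimators: for biallelic diploid data the two converge, and W-C has a
closed per-locus form that the tests verify by hand. Note θ̂ is not
unbiased at literal sample duplication (bias ≈ −1/(2(n−1))); the
panmictic-null calibration uses independent draws. Significance: 10,000
permutations of individuals between the two populations, sizes
preserved, p = (count(θ̂* ≥ θ̂) + 1)/(n_perm + 1).

## Regression suite

Four responses (Procrustes distance to source, within-lake shape
variance, CV_ei, and rate = Mahalanobis distance / colonisation time in
generations — a multivariate analogue of the haldane) against six
predictors (founder size, colonisation time, admixture proportion,
long-term Ne, mean depth, littoral-zone area), each as a *separate*
simple OLS fit: with only ~6 lakes, multipredictor models are not
estimable. Founder size is always log10-transformed (it spans two orders
of magnitude); "exponential" variants (log10 predictor) are additionally
fitted for shape variance ~ depth and rate ~ time. Surface area is
accepted as a column but excluded from the default predictor set because
it is collinear with mean depth. p-values are two-sided F-tests
(equal to squared-t for simple regression); no multiple-testing
correction is applied to the primary column, but a Bonferroni column is
emitted for transparency. Adjusted R² uses 1 − (1 − R²)(n − 1)/(n − 2).
A constant response returns an error-free fit with R² = 0, p = 1.

## Synthetic data

The generators define the conditions the package validates itself under.

*Landmarks*: a 12-landmark lateral fish outline; per specimen
flat shape = base + group offset + slope·(log₁₀CS − mean) + isotropic
Gaussian landmark noise (default sd 0.02 shape units), scaled so its
centroid size equals a log-normal draw (median 10, log-sd 0.25), then
randomly rotated and translated. Group offsets are constructed orthogonal
to the similarity tangent space (translation/rotation/scaling directions
at the base shape) so that planted effects pass through superimposition
and are recoverable — the `elongation_offset` helper plants the
slender-body direction the radiation's main axis corresponds to. The
per-photograph nuisance *scale* is stored as the TPS SCALE factor rather
than baked into the coordinates: a random multiplicative scale inside the
coordinates would be indistinguishable from biological size and would
destroy the centroid-size signal the pooled allometry regression is
supposed to recover. Allometry enters before the nuisance transforms,
mirroring how real size variation arises.

*Genotypes*: four populations on the fixed topology (((W, X), Y), Z);
ancestral frequencies Beta(0.8, 0.8), per-branch truncated-Gaussian
frequency drift (defaults: 0.05 on the recent branches, 0.10 to Y, 0.20
to the outgroup — a cheap stand-in for generations of genetic drift that
is sufficient for sign and calibration behaviour; coalescent machinery is
out of scope), an admixture pulse replacing fraction f of W's ancestry
with Y's frequencies, and binomial(2, p) genotypes. Default sample sizes
10/10/10/5 emulate a crater-lake quartet with a small outgroup panel.

*Lake tables*: predictors drawn log-uniformly over crater-lake-like
ranges (founder size 30–9000 individuals, colonisation 500–1700
generations, admixture 0.04–0.33, Ne 1000–9000, mean depth 17–142 m,
littoral zone 0.1–10 km²) with one planted linear (or log-linear)
predictor–response relation.

What the generators do **not** emulate: landmark digitisation error
structure (correlated, landmark-specific), integer pixel quantisation,
linkage disequilibrium between SNPs, within-locus SNP correlation, and
selection. Passing tests therefore demonstrate correctness of the
estimators and calibration of the tests under idealised sampling noise,
not robustness to those real-data features.

## Problem sizes and calibration conditions

The self-validation suite uses 30 specimens per group for planted-effect
recovery (typical of per-population sample sizes in such studies); 500
null replicates at 199 permutations each for the type-I calibration of
the dL and F_ST permutation tests (the 199+1 grid makes the 0.05
threshold exactly attainable); 100 null replicates of 2000 SNPs for
D-statistic Z coverage; and 13,526 SNPs — a realistic post-filtering
RADseq panel size — for admixture power at f = 0.2. The acceptance
script re-runs all of these from a single seed.

## Known limitations

- Landmark schemes other than 12×2D work throughout the core, but the
  elongation-index defaults and the wireframe plot assume the packaged
  scheme.
- The D-statistic's SNP-count blocks understate SEs when LD is strongly
  heterogeneous; supply larger blocks in that case.
- bgPCA scores are known to exaggerate group separation when p ≫ n; the
  package reports it (as the visual convention of this literature
  expects) but all inference runs on the raw corrected coordinates.
- The wireframe deformation plot is a convenience visualisation and is
  not validated by tests.
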