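# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic-data generators do and do not emulate, and
the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Gradient pipeline

**Thresholding.** `threshold_rows` keeps, per row, the `ceil(density·(n−1))`
largest off-diagonal entries (default density 0.10, i.e. 90% of each row
zeroed) and zeroes the diagonal. The output is generally asymmetric — each
row keeps its own strongest connections. Ties at the boundary are broken by
(value descending, column index ascending), which is deterministic across
platforms; a strict mode (`tie_policy="error"`) raises instead. Whether the
input connectivity is Fisher z-transformed beforehand is left to the caller:
row-wise proportional thresholding and the normalized angle are both
invariant to any monotone transform applied uniformly, except through the
retained values' magnitudes, and the package accepts either convention.

**Affinity.** `normalized_angle` maps cosine similarity between thresholded
rows through `1 − arccos(·)/π`, giving 1 for identical, 0.5 for orthogonal
and 0 for anti-parallel rows. The result is symmetrized (numerical
round-off only), unit-diagonal and clipped to [0, 1].

**Diffusion map.** The affinity is density-normalized with exponent
α = 0.5 (`W = D^−α A D^−α`, D = row degree) — the half-way point between
maximal (α = 0) and no (α = 1) influence of sampling density — then
row-normalized into a Markov operator. Eigendecomposition is performed on
the symmetric conjugate `D_w^−1/2 W D_w^−1/2` for numerical stability and
back-transformed to right eigenvectors, normalized to the unit-norm
right-eigenvector convention with the trivial eigenvector rescaled to the
constant one; this matches the convention of the widely used reference
implementations, and a dense nonsymmetric eigendecomposition of the Markov
operator is kept as an independent oracle in the tests. At diffusion time
t = 0 the multiscale convention scales component i by λᵢ/(1−λᵢ); t > 0
uses λᵢᵗ. Components are ordered by eigenvalue, and
`variance_explained_i = λᵢ²/Σλ²` over the nontrivial spectrum. A
disconnected affinity graph raises `GraphError`; a nontrivial eigenvalue at
1 raises `NumericalError`.

**Alignment and eccentricity.** `procrustes_align` applies one orthogonal
transform (rotation/reflection, no scaling or translation) minimizing the
Frobenius distance between the first `n_components` score columns; it
preserves all pairwise distances within an embedding. The shipped reference
embedding is synthetic — generated at run time from a fixed, documented
seed — and any user-supplied embedding can replace it. Eccentricity is the
Euclidean norm of (G1, G2, G3) relative to the per-subject centroid
(default) or the origin of the aligned space; both centers are exposed
because either reading of "individual center" is defensible, and the
center used is recorded. Eccentricity uses the λ-scaled aligned scores,
consistent with the embedding convention.

**Recovery properties.** On a synthetic kernel connectome over latent 3D
positions, the embedding recovers the positions up to an orthogonal
transform and global scale. The validation suite measures Tucker congruence
after an orthogonal-Procrustes fit, embedding the dense connectome
(density 1): proportional thresholding exists to sparsify noisy empirical
connectivity, and on a noise-free kernel affinity it only discards
geometry. The congruence of the full default-density pipeline is reported
alongside as its own quantity; it is systematically lower because the 10%
threshold makes the graph local, and the diffusion eigenfunctions of a
bounded domain are boundary-flattened warps of the coordinates.

## Equivolumetric profiling

Vertex areas follow the thirds rule (each triangle contributes one third of
its area to each corner), so per-vertex areas sum exactly to the mesh area.
The distance fraction for volume fraction α is the closed form above,
derived from setting the cumulative volume of a linearly varying column,
`V(ρ) = A_in·ρ + ρ²(A_out−A_in)/2`, equal to α·V(1); when
`|A_out − A_in| < 1e−12·max(A_in, A_out)` the analytic limit ρ = α is
returned. ρ is monotone in α and clipped to [0, 1].

The 12 surfaces use volume fractions i/13 (i = 1..12): strictly
intracortical, excluding the pial and white boundaries themselves; the
alternative centered convention (i−0.5)/12 is selectable. α is measured
from the white surface toward pial; **depth index 1 is the most superficial
(pial-adjacent) surface**, so that the compartment grouping superficial =
depths 1–4, middle = 5–8, deep = 9–12 reads outward-in. Intermediate
vertices sit on the straight segment joining corresponding white/pial
vertices (the linked-vertex setting); no streamlines are solved, and
self-intersections of the output are not repaired (a per-vertex
monotonicity check is logged instead).

Volume sampling is trilinear (`scipy.ndimage.map_coordinates`, order 1) in
world coordinates through the NIfTI affine; analytic fields are evaluated
exactly. Out-of-bounds vertices are marked missing; more than 5% missing is
an error. Parcel profiles are means over assigned, non-missing vertices
with pairwise deletion; parcels with fewer than 10 fully valid vertices are
flagged low-confidence. Depth z-scores standardize each depth column across
parcels with the population (n) denominator. On wedge fixtures whose
cross-sectional area varies linearly along the column the placement is
analytically exact, which is why the volume-conservation check can demand
1e-3 relative error (measured: float round-off).

## Longitudinal mixed models

Change maps subtract metric maps of consecutive scans per subject; each row
carries the module trained during that interval ("None" for untrained
intervals) and the covariates of the later scan. Intervals with a missing
endpoint are dropped and counted.

The per-parcel model is `Δ ~ 1 + centered age + sex + interval_index + TM`
with a subject random intercept, fit by REML. The interval-index covariate
(scans since baseline) is the package's reading of the design's
repeated-measurement term and can be toggled off. Because thousands of
parcels share one design matrix, the solver profiles the variance ratio
λ = σ_b²/σ_e² per parcel: with a random intercept, every GLS quantity
reduces to per-group sums, leaving a bounded one-dimensional REML
optimization per parcel (the λ = 0 boundary is always a candidate, so
singular fits fall back to OLS). This is the massively univariate design
used by surface-statistics toolboxes; the tests cross-check it against a
generic mixed-model implementation to ~1e-5 in coefficients and variance
components. Module comparisons pool both training cohorts' intervals for
the same module; the control contrast compares a module against untrained
retest intervals.

Inference: Wald t for the module indicator; two-sided p on a t distribution
with `df = n_obs − p_fixed` (residual degrees of freedom of the fixed
design, not Satterthwaite — the convention of the surface-statistics
family, and the one under which `d = t/√df` is the reported effect size);
BH-FDR across parcels within one contrast (the multiple-testing family
matches figure-level reporting; no cross-contrast correction). With ~400
rows the practical difference from Satterthwaite df is negligible (t
critical values differ in the third decimal), and the validation suite
verifies type-I error calibration directly. An optional per-parcel
covariate column (e.g. concurrent thickness change) is supported; it
switches to a slower per-parcel fit because the design then differs across
parcels.

## Spin tests

Rotations are Haar-uniform (`scipy.stats.special_ortho_group`); with
hemisphere labels, the right hemisphere receives the x-mirrored rotation.
Reassignment is nearest rotated centroid by maximal inner product on the
unit sphere. The p-value uses the (1 + exceedances)/(n_perm + 1) counting
rule, two-sided on |r| by default. Map correlations are Pearson,
pairwise-complete over NaNs.

The calibration study draws pairs of independent maps with matched
autocorrelation: white noise on near-uniform sphere parcels convolved with
a Gaussian kernel of length scale 0.6 (chordal, unit sphere), standardized
per map. At this smoothing a naive parametric correlation test rejects the
true null far above its nominal level, while the spin test stays near 5%.
Measured over thousands of replicates, the spin test's true rejection rate
at α = 0.05 is ≈ 0.059 at both 200 and 400 parcels — the mild
anti-conservatism known for discrete nearest-centroid reassignment under
strong autocorrelation (rotated assignments duplicate some parcels and drop
others, slightly under-dispersing the null). Users should treat p_spin
values very near the threshold accordingly. Variogram-matching surrogate
methods are out of scope but would be the natural extension.

## Behavioral prediction

Residualization fits each feature on (1, age, sex) by OLS on training rows
only and applies the training coefficients to test rows — the leakage
control. Age and sex are never candidate predictors. Greedy forward
selection scores candidates by training-set MAE of a lasso at a fixed
mid-grid penalty (1e-2; the greedy pass deliberately uses no inner
cross-validation), adding features until 20% (7 of 35) are kept; ties break
to the lowest index, making selection deterministic. The final penalty is
re-tuned per fold by 5-fold inner cross-validation over a 100-point log
grid on [1e-4, 1] with L1 ratio 1 (a lasso), then refit on all training
rows. Fold assignment is a fresh uniform shuffle per repeat with seeds
derived from the master seed; results are bit-reproducible given (seed,
data).

Per repeat the package reports both the pooled correlation between actual
and predicted scores and the fold-averaged correlation. Pooled r carries a
known artifact: when a model degenerates to near-constant per-fold
predictions (training means), the complementary-subset structure of
cross-validation anti-correlates those constants with the held-out means,
biasing pooled null r negative (≈ −0.17 in the leakage experiment's
strongly nuisance-driven setting). The leakage experiment therefore
compares fold-averaged null correlations: in-fold residualization keeps
them at zero; full-sample residualization of features and target before
cross-validation corrupts the null with a data-dependent bias of either
sign; omitting residualization entirely lets the model predict the
nuisance-driven target through the confounded features (r ≈ 0.7–0.9).
nMAE is −MAE on the behavior's native scale, with no normalization.

Specificity analyses run the identical pipeline (same fold seeds, hence
paired repeats) on alternative targets — permuted scores, off-domain
behavior — and compare per-repeat r distributions with a sign-flip
permutation test on the paired differences.

## Synthetic-data generators: what they emulate, and what not

*Connectomes* are Gaussian kernels `exp(−d²/scale)` over latent 3D parcel
positions sampled uniformly from the unit ball (isotropic; a cube's
corners distort spectral recovery), plus symmetric Gaussian noise, clipped
to [−1, 1] with unit diagonal. This reproduces the one property the
gradient stage relies on — a low-dimensional latent geometry expressed in
connectivity — but not the heavy-tailed, block-structured, globally
signed correlation structure of empirical functional connectivity.

*Cohorts* follow the crossover design: both training cohorts start with the
attention module and swap the order of the socio-affective and
socio-cognitive modules; the retest control cohort is scanned on the same
schedule untrained; an optional further cohort completes a single
socio-affective module. Per interval,
`map(T_{k+1}) = map(T_k) + effect_map(module) + subject_drift + noise`,
with the drift constant per subject (what the random intercept on change
scores absorbs) and noise independent per interval and parcel. Ages are
uniform on 20–55 years and sex is Bernoulli with rate 0.59 (female = 1),
used only as nuisance structure; no module × age interactions are
generated. Defaults mirror the study's scale: 400 parcels, on the order of
100 subjects per arm, module effects of 0.2 metric units in 40 parcels,
drift and noise scales 0.1. Dropout, motion, scanner drift and
cohort-by-site structure are not simulated, so passing tests demonstrate
statistical correctness of the machinery, not robustness to those
artifacts.

*Cortex fixtures* are analytic: flat and sinusoidal sheets (constant
thickness along the normal), a wedge whose outer/inner area ratio is exact
per column with cross-sectional area linear in depth (making equivolume
placement exactly solvable — the oracle geometry), and concentric sphere
patches. *qT1 fields* are analytic functions of depth fraction and region,
rasterizable to NIfTI; values around 1400–1900 ms mimic the plausible
cortical range, with qT1 increasing toward the white surface left to the
caller's profile.

*Behavior* is `y = Xw + ε` with 7 of 35 nonzero weights of 0.075 each and
noise set to reach the stated population R². The weight scale matters: it
puts the target's standard deviation near 0.3, the small native scale of
behavioral change scores, for which the fixed [1e-4, 1] lasso grid brackets
the optimal penalty. On unit-scale targets the same grid saturates at its
upper end and the model collapses to the null — a real interaction between
target scaling and a fixed penalty grid that users of the pipeline should
know about.

## Problem sizes in the validation suite

The simulation studies run at: 30 random matrices (n ≤ 50) for the
embedding oracle; 400 parcels for manifold recovery and the equivolume
wedge; 2000 parcels × 100 subjects/arm for null calibration; 1000
replicates for empirical FDR (80% true nulls, so the expected FDR is
0.8 × q); 200 parcels for planted-effect recovery (the planted per-parcel
change is derived from the realized design via δ = d·SE·√df, since a
population d is only defined through the design); 500 replicates × 500
rotations at 200 parcels for spin calibration; 11 replicate datasets
(n = 100, 5 folds × 10 repeats) for prediction recovery, 50 fresh
permutations for the shuffled null, and 4 datasets × 3 variants for the
leakage experiment; the determinism check runs a reduced pipeline twice
(60 parcels, 8 subjects/arm). The full default pipeline (400 parcels, 100
subjects/arm, 1000 rotations, 100 repeats) runs in well under 15 minutes on
one CPU.

## Known limitations

- Gradient recovery through the default 10% row threshold is intentionally
  reported but not asserted; local graphs warp bounded-domain coordinates.
- The residual-df Wald inference is calibrated at the study's sample sizes
  but would be anti-conservative for very small cohorts; a Satterthwaite
  option would be the next refinement.
- The spin test's discrete reassignment is mildly anti-conservative under
  strong smoothing (measured ≈ 0.059 at nominal 0.05).
- Greedy forward selection at population R² = 0.3 with 7 equal weak signals
  is information-limited: even oracle marginal ranking recovers a median of
  5 of 7 true features; the pipeline matches that ceiling rather than
  beating it.
- Mesh self-intersection of laminar stacks on thin or noisy cortices is
  logged, not repaired.
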