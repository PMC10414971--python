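# gradplast

Longitudinal analysis of cortical functional organization and intracortical
microstructure, built for crossover training studies: connectome **gradients**
and **eccentricity**, **equivolumetric** qT1 depth profiles, per-parcel
**mixed-effects** training contrasts with FDR, **spin-permutation** tests of
spatial correspondence, and leakage-controlled **lasso prediction** of
behavioral change — all exercisable end to end on synthetic cohorts with
planted ground truth.

## Who this is for

Researchers analyzing repeated-measures neuroimaging designs in which groups
of participants complete different interventions in different orders (here: a
contemplative-training design with an attention module, a socio-affective
module and a socio-cognitive module, plus an untrained retest control
cohort), and who want every stage — from connectivity matrix to
brain-behavior prediction — reproducible, seeded and testable without access
to the original human data.

## The methods

**Gradients and eccentricity.** A parcel-by-parcel functional connectivity
matrix is proportionally thresholded per row (top 10% of connections kept),
converted to a normalized-angle affinity
`a_ij = 1 − arccos(cos_sim(row_i, row_j))/π`, and embedded by a diffusion map
(density normalization `W = D^−α A D^−α` with α = 0.5, multiscale scaling
λ/(1−λ) at diffusion time t = 0). Individual embeddings are aligned to a
reference by orthogonal Procrustes rotation. Eccentricity condenses the first
three gradients G1–G3 into one scalar per parcel: the Euclidean distance to
the centroid of the 3D gradient space — low for functionally integrated
parcels, high for segregated ones.

**Equivolumetric depth profiles.** Between paired white and pial surfaces, 12
intracortical surfaces are placed so that each encloses a fixed fraction of
the local cortical volume. For a column whose cross-sectional area varies
linearly from the inner area `A_in` to the outer area `A_out`, the distance
fraction enclosing volume fraction α is

    ρ = (−A_in + √(α·A_out² + (1−α)·A_in²)) / (A_out − A_in),

with ρ = α in the flat limit `A_out = A_in`. Quantitative T1 (ms) is sampled
at every surface vertex, averaged per parcel and depth, and grouped into
superficial (depths 1–4), middle (5–8) and deep (9–12) compartments.

**Training contrasts.** Subject-specific change maps (differences of
consecutive scans) enter a per-parcel linear mixed model
`Δ ~ 1 + age + sex + interval_index + TM + (1 | subject)` fit by REML; the
training-module contrast is a Wald t with residual degrees of freedom of the
fixed design, effect size `d = t/√df`, and Benjamini–Hochberg FDR across
parcels.

**Spin tests.** The correlation between two parcel maps is tested against a
null built by Haar-uniform rotations of the parcel centroids on the sphere
(mirrored across hemispheres), which preserves each map's spatial
autocorrelation; `p_spin = (1 + #{|r_null| ≥ |r_obs|}) / (n_perm + 1)`.

**Behavioral prediction.** 35 features (5 a-priori networks × {Δeccentricity,
ΔG1–G3, ΔqT1 superficial/middle/deep}) predict a behavior-change score via
five-fold cross-validation repeated with fresh shuffles: in each fold, age
and sex are regressed out of the features on training rows only, greedy
forward selection keeps the top 20% (7) of features by training MAE, and a
lasso with an inner-CV penalty on a 100-point log grid in [1e-4, 1] is fit.
Accuracy is the pooled out-of-sample Pearson r and negative mean absolute
error (nMAE) per repeat.

## Worked example

`examples/training_contrasts.py` simulates a crossover cohort (80 subjects
per arm) with an eccentricity increase of 0.2 planted in 20 of 100 parcels
for the attention module only, and contrasts it against the socio-cognitive
module:

```
contrast Presence vs Perspective: df = 315
FDR q<0.05 discoveries: 9 (9 of 20 planted, 0 false)
mean estimated effect in planted parcels: 0.197 (planted 0.2)
largest effect size d = 0.272 at parcel 9
```

The model recovers the planted mean change (0.197 vs 0.2) with zero false
discoveries at FDR q < 0.05; at this sample size and noise level 9 of the 20
planted parcels reach significance. `examples/behavior_prediction.py` plants
a sparse 7-of-35 brain-behavior signal at population R² = 0.3 and prints

```
out-of-sample r = 0.320 +/- 0.061 (100% of repeats positive)
nMAE = -0.290 +/- 0.010
```

with the true features dominating the selection frequencies. The other
examples demonstrate gradient embedding and eccentricity, equivolumetric
profiling on a wedge cortex, spin testing, and the one-command pipeline
(`gradplast run --config study.yaml --seed 5 --out runs/demo`), which writes
per-stage tables plus a provenance manifest and is byte-reproducible given
the seed.

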