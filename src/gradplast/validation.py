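"""Simulation studies validating every stage against planted ground truth.

Each function runs one self-contained experiment — embedding-oracle
equivalence, latent-manifold recovery, equivolume volume conservation,
mixed-model and spin-test calibration, planted-effect and sparse-signal
recovery, leakage control, pipeline determinism — and returns the measured
quantities. The test suite asserts on them and the reproducibility script
reports them; both therefore exercise identical code paths.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.stats

from .equivolume import build_laminar_stack, equivolume_fraction
from .gradients import AffinityMatrix, diffusion_embedding, normalized_angle, threshold_rows
from .io_core import RunConfig, child_seeds, rng_from_seed
from .longitudinal import change_maps, fdr_bh, fit_contrast
from .pipeline import run_pipeline
from .prediction import cross_validate, residualize_in_fold
from .spatial import spatial_corr, spin_test
from .synthetic import (
    EffectSpec,
    LatentManifold,
    make_cohort,
    make_connectome,
    make_cortex,
    make_smooth_sphere_maps,
)

__all__ = [
    "procrustes_congruence",
    "embedding_oracle_deviation",
    "manifold_recovery",
    "equivolume_conservation",
    "null_calibration",
    "fdr_calibration",
    "effect_recovery",
    "spin_calibration",
    "prediction_recovery",
    "shuffled_target_null",
    "leakage_experiment",
    "determinism_check",
]


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def procrustes_congruence(scores: np.ndarray, target: np.ndarray) -> float:
    """Tucker congruence after an orthogonal-Procrustes fit with global scale."""
    A = scores - scores.mean(axis=0)
    B = target - target.mean(axis=0)
    Q, s = scipy.linalg.orthogonal_procrustes(A, B)
    Ahat = (s / np.sum(A**2)) * (A @ Q)
    return float(np.sum(Ahat * B) / np.sqrt(np.sum(Ahat**2) * np.sum(B**2)))


def _dense_embedding_oracle(A: np.ndarray, alpha: float, k: int):
    """Brute-force diffusion map via nonsymmetric eig of the transition operator.

    Independent route: density-normalize, row-normalize, ``scipy.linalg.eig``
    on the (nonsymmetric) Markov operator, normalize the trivial eigenvector
    to ones, drop it, and apply the multiscale ``lambda / (1 - lambda)``
    scaling.
    """
    d = A.sum(axis=1)
    K = A / np.outer(d**alpha, d**alpha)
    P = K / K.sum(axis=1, keepdims=True)
    lam, U = scipy.linalg.eig(P)
    lam, U = np.real(lam), np.real(U)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    psi = U / U[:, [0]]
    lam_nt = lam[1:k + 1]
    return psi[:, 1:k + 1] * (lam_nt / (1 - lam_nt))[None, :], lam_nt


def embedding_oracle_deviation(n_matrices: int = 30, seed: int = 0,
                               max_n: int = 50, k: int = 8) -> dict:
    """Max deviation between the embedding and the dense brute-force oracle.

    Random dense symmetric affinities (n <= ``max_n``); scores are compared
    after orthogonal alignment (which absorbs signs, permutations of
    near-degenerate pairs, and rotations within them), eigenvalues directly.
    """
    seeds = child_seeds(seed, n_matrices)
    max_score_dev = 0.0
    max_eig_dev = 0.0
    for s in seeds:
        rng = rng_from_seed(int(s))
        n = int(rng.integers(20, max_n + 1))
        raw = rng.uniform(0.0, 1.0, size=(n, n))
        A = 0.5 * (raw + raw.T)
        np.fill_diagonal(A, 1.0)
        emb = diffusion_embedding(AffinityMatrix(values=A), k=k)
        oracle_scores, oracle_lam = _dense_embedding_oracle(A, alpha=0.5, k=k)
        max_eig_dev = max(max_eig_dev, float(np.abs(emb.eigenvalues - oracle_lam).max()))
        Q, _ = scipy.linalg.orthogonal_procrustes(oracle_scores, emb.scores)
        max_score_dev = max(max_score_dev,
                            float(np.abs(oracle_scores @ Q - emb.scores).max()))
    return {"max_score_dev": max_score_dev, "max_eigenvalue_dev": max_eig_dev}


def manifold_recovery(seed: int = 0, n_parcels: int = 400, noise_sd: float = 0.01,
                      density: float = 1.0) -> float:
    """Congruence between embedded gradients and the generating 3D coordinates.

    The default embeds the dense kernel connectome (``density=1``):
    proportional thresholding exists to sparsify noisy empirical FC, and on
    a clean kernel affinity it only discards geometry. Pass ``density=0.10``
    to measure recovery through the full default pipeline instead.
    """
    manifold = LatentManifold.random(n_parcels, seed=seed, kernel_scale=1.0,
                                     noise_sd=noise_sd)
    cm, coords = make_connectome(manifold, seed=seed)
    emb = diffusion_embedding(normalized_angle(threshold_rows(cm, density=density)), k=10)
    return procrustes_congruence(emb.scores[:, :3], coords)


# ---------------------------------------------------------------------------
# equivolume
# ---------------------------------------------------------------------------

def _solid_volume(va: np.ndarray, vb: np.ndarray, faces: np.ndarray) -> float:
    """Volume of the ruled solid between two corresponding triangulated surfaces
    (numeric integration by tetrahedral decomposition of each triangular prism)."""
    a0, a1, a2 = va[faces[:, 0]], va[faces[:, 1]], va[faces[:, 2]]
    b0, b1, b2 = vb[faces[:, 0]], vb[faces[:, 1]], vb[faces[:, 2]]
    vol = 0.0
    for p0, p1, p2, p3 in ((a0, a1, a2, b0), (a1, a2, b0, b1), (a2, b0, b1, b2)):
        vol += np.abs(np.einsum("ij,ij->i", np.cross(p1 - p0, p2 - p0), p3 - p0)).sum() / 6.0
    return float(vol)


def equivolume_conservation(n_vertices: int = 400, area_ratio: float = 2.0,
                            n_surfaces: int = 12) -> dict:
    """Volume conservation on a wedge plus closed-form checks of rho.

    Returns the relative spread of the fractional volumes between the
    ``n_surfaces + 1`` gaps of a wedge stack (area varying linearly along
    the column), the deviation of ``rho(1, 2, 0.5)`` from the positive root
    of the cumulative-volume quadratic, and the maximal displacement of an
    equal-area (flat) stack from equidistant placement.
    """
    sp = make_cortex("wedge", n_vertices=n_vertices, thickness=3.0, area_ratio=area_ratio)
    stack = build_laminar_stack(sp, n_surfaces=n_surfaces)
    surfs = [sp.pial_vertices, *stack.surfaces, sp.white_vertices]
    vols = np.array([_solid_volume(surfs[i], surfs[i + 1], sp.faces)
                     for i in range(n_surfaces + 1)])
    rel_spread = float((vols.max() - vols.min()) / vols.mean())

    rho_dev = abs(equivolume_fraction(1.0, 2.0, 0.5) - (np.sqrt(2.5) - 1.0))

    flat = make_cortex("sheet", n_vertices=n_vertices, thickness=3.0)
    fstack = build_laminar_stack(flat, n_surfaces=n_surfaces)
    fracs = fstack.volume_fractions
    expected = flat.white_vertices[None] + fracs[:, None, None] * (
        flat.pial_vertices - flat.white_vertices)[None]
    flat_dev = float(np.abs(fstack.surfaces - expected).max() / 3.0)
    return {"volume_rel_spread": rel_spread, "rho_example_dev": float(rho_dev),
            "flat_limit_max_dev": flat_dev}


# ---------------------------------------------------------------------------
# longitudinal statistics
# ---------------------------------------------------------------------------

def null_calibration(seed: int = 0, n_parcels: int = 2000, n_per_arm: int = 100,
                     subject_sd: float = 0.1, residual_sd: float = 0.3) -> dict:
    """Type-I error of the mixed-model contrast under the null cohort generator.

    No effects are planted; each parcel is an independent realization of
    subject drift plus interval noise. Returns the parcel-wise rejection
    rate at p < 0.05 for the Presence-vs-Perspective contrast and the
    fraction of BH-FDR discoveries at q < 0.05 (expected 0).
    """
    spec = EffectSpec.null(n_parcels, subject_sd=subject_sd, residual_sd=residual_sd)
    design, maps = make_cohort(n_per_arm, n_per_arm, n_per_arm, spec,
                               n_parcels=n_parcels, seed=seed)
    ct = change_maps(maps, design)
    res = fit_contrast(ct, ("Presence", "Perspective"))
    return {
        "rejection_rate": float(np.mean(res.p < 0.05)),
        "fdr_discovery_rate": float(np.mean(res.q < 0.05)),
        "df": res.df,
    }


def fdr_calibration(seed: int = 0, n_reps: int = 1000, m: int = 200,
                    frac_null: float = 0.8, effect_z: float = 4.0,
                    q: float = 0.05) -> float:
    """Empirical false discovery rate of BH over replicate mixed batteries.

    Per replicate, ``frac_null`` of the m tests are true nulls (uniform p)
    and the rest carry a shifted-normal signal; the realized V/max(R, 1) is
    averaged over replicates. Expected value is at most ``q * frac_null``.
    """
    rng = rng_from_seed(seed)
    m0 = int(round(frac_null * m))
    fdps = np.empty(n_reps)
    for i in range(n_reps):
        z = rng.standard_normal(m)
        z[m0:] += effect_z
        p = 2 * scipy.stats.norm.sf(np.abs(z))
        reject, _ = fdr_bh(p, q)
        v = int(reject[:m0].sum())
        r = int(reject.sum())
        fdps[i] = v / max(r, 1)
    return float(fdps.mean())


def effect_recovery(seed: int = 0, n_parcels: int = 200, n_per_arm: int = 100,
                    target_d: float = 0.25, subject_sd: float = 0.1,
                    residual_sd: float = 0.3) -> dict:
    """Recovery of a planted training contrast of known population effect size.

    The per-parcel effect is derived from the realized design by the power
    identity ``delta = d * SE_true * sqrt(df)`` (the population d of a
    contrast is only defined through the design), planted on every parcel
    for the Presence module, and re-estimated; returns the mean estimated d,
    its Monte-Carlo standard error across parcels, and the target.
    """
    # realized design (ages, sexes, cohort structure) from a null cohort
    spec0 = EffectSpec.null(1, subject_sd=subject_sd, residual_sd=residual_sd)
    design, maps0 = make_cohort(n_per_arm, n_per_arm, n_per_arm, spec0,
                                n_parcels=1, seed=seed)
    ct0 = change_maps(maps0, design)
    keep = (ct0.frame["tm"] == "Presence") | (ct0.frame["tm"] == "Perspective")
    frame = ct0.frame.loc[keep]
    age = frame["age"].to_numpy(float)
    X = np.column_stack([
        np.ones(keep.sum()), age - age.mean(), frame["sex"].to_numpy(float),
        frame["interval_index"].to_numpy(float),
        (frame["tm"] == "Presence").to_numpy(float),
    ])
    groups = frame["subject_id"].to_numpy()
    # true-lambda GLS standard error of the contrast on this design
    lam = (subject_sd / residual_sd) ** 2
    _, grp = np.unique(groups, return_inverse=True)
    n_g = np.bincount(grp).astype(float)
    S = np.zeros((len(n_g), X.shape[1]))
    np.add.at(S, grp, X)
    w = lam / (1 + lam * n_g)
    XtVX = X.T @ X - (S.T * w) @ S
    c = np.zeros(X.shape[1])
    c[-1] = 1.0
    se_true = residual_sd * np.sqrt(c @ np.linalg.solve(XtVX, c))
    df = X.shape[0] - X.shape[1]
    delta = target_d * se_true * np.sqrt(df)

    effect = np.full(n_parcels, float(delta))
    spec = EffectSpec(effect_maps={"Presence": effect,
                                   "Affect": np.zeros(n_parcels),
                                   "Perspective": np.zeros(n_parcels)},
                      subject_sd=subject_sd, residual_sd=residual_sd)
    design, maps = make_cohort(n_per_arm, n_per_arm, n_per_arm, spec,
                               n_parcels=n_parcels, seed=seed)
    res = fit_contrast(change_maps(maps, design), ("Presence", "Perspective"))
    return {
        "mean_d": float(res.d.mean()),
        "target_d": float(target_d),
        "mc_se": float(res.d.std(ddof=1) / np.sqrt(n_parcels)),
        "planted_delta": float(delta),
    }


# ---------------------------------------------------------------------------
# spatial statistics
# ---------------------------------------------------------------------------

def spin_calibration(seed: int = 0, n_reps: int = 500, n_perm: int = 500,
                     n_parcels: int = 200, smoothing: float = 0.6) -> dict:
    """False-positive rates of the spin test vs a naive parametric test.

    Pairs of independent maps with matched spatial autocorrelation
    (kernel-smoothed noise on the sphere) are tested at alpha = 0.05; the
    spin test should stay near 0.05 while the parametric correlation test
    over-rejects because it treats autocorrelated parcels as independent.
    """
    seeds = child_seeds(seed, n_reps)
    rej_spin = 0
    rej_naive = 0
    for i in range(n_reps):
        s = int(seeds[i])
        coords, maps = make_smooth_sphere_maps(n_parcels, 2, seed=s, smoothing=smoothing)
        a, b = maps
        rej_spin += spin_test(a, b, coords, n_perm=n_perm, seed=s + 1).p_spin < 0.05
        r = spatial_corr(a, b)
        t = r * np.sqrt((n_parcels - 2) / (1 - r**2))
        p_naive = 2 * scipy.stats.t.sf(abs(t), n_parcels - 2)
        rej_naive += p_naive < 0.05
    return {"spin_rejection_rate": rej_spin / n_reps,
            "naive_rejection_rate": rej_naive / n_reps,
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _planted_dataset(seed: int, n: int = 100, p: int = 35, k: int = 7,
                     weight: float = 0.075, r2: float = 0.3):
    """Sparse linear brain-behavior dataset at a stated population R^2."""
    rng = rng_from_seed(seed)
    X = rng.standard_normal((n, p))
    support = rng.choice(p, size=k, replace=False)
    w = np.zeros(p)
    w[support] = weight
    noise_sd = float(np.sqrt(np.sum(w**2) * (1 - r2) / r2))
    y = X @ w + rng.normal(0.0, noise_sd, n)
    return X, y, support


def prediction_recovery(seed: int = 0, n_datasets: int = 9, reps: int = 10,
                        folds: int = 5, r2: float = 0.3) -> dict:
    """Out-of-sample accuracy and support recovery on planted sparse signals.

    Each replicate dataset plants 7 of 35 features at population R^2
    ``r2`` (n = 100); the full pipeline (in-fold selection and penalty
    tuning) is run and a dataset's recall is the overlap between its 7
    most frequently selected features and the true support.
    """
    seeds = child_seeds(seed, n_datasets)
    all_r, recalls = [], []
    for i in range(n_datasets):
        X, y, support = _planted_dataset(int(seeds[i]))
        res = cross_validate(X, y, folds=folds, reps=reps, seed=int(seeds[i]) + 1)
        all_r.append(res.per_repeat_r)
        top = np.argsort(res.selection_frequency)[-len(support):]
        recalls.append(len(set(top.tolist()) & set(support.tolist())))
    all_r = np.concatenate(all_r)
    return {
        "mean_r": float(all_r.mean()),
        "frac_positive_repeats": float(np.mean(all_r > 0)),
        "median_recall": float(np.median(recalls)),
        "recalls": recalls,
    }


def shuffled_target_null(seed: int = 0, n_shuffles: int = 50, folds: int = 5) -> dict:
    """Permutation null of the prediction pipeline: fresh shuffle per repeat."""
    X, y, _ = _planted_dataset(seed)
    rng = rng_from_seed(seed + 1)
    rs = np.empty(n_shuffles)
    for i in range(n_shuffles):
        yp = rng.permutation(y)
        res = cross_validate(X, yp, folds=folds, reps=1, seed=seed + 2 + i)
        rs[i] = res.per_repeat_r[0]
    return {"mean_r": float(rs.mean()), "sd_r": float(rs.std(ddof=1))}


def leakage_experiment(seed: int = 0, n_datasets: int = 4, reps: int = 3,
                       folds: int = 5) -> dict:
    """Nuisance-leakage regression experiment.

    Features are collinear with age/sex and the target is driven by
    age/sex only (no direct brain-behavior link). Three pipelines run on
    identical data: in-fold residualization (correct), full-sample
    residualization of features and target before cross-validation
    (leaky), and no residualization at all (confounded). Fold-averaged
    null correlations are reported: the correct pipeline stays at zero,
    the leaky one is biased away from zero with data-dependent sign, and
    the confounded one is grossly inflated.
    """
    seeds = child_seeds(seed, n_datasets)
    devs = {"in_loop": [], "out_of_loop": [], "none": []}
    for i in range(n_datasets):
        rng = rng_from_seed(int(seeds[i]))
        n, p = 100, 35
        age = rng.uniform(20.0, 55.0, n)
        sex = rng.integers(0, 2, n).astype(float)
        Z = np.column_stack([(age - age.mean()) / age.std(), sex - sex.mean()])
        X = Z @ rng.standard_normal((2, p)) + rng.standard_normal((n, p))
        y = Z @ np.array([0.2, 0.2]) + 0.15 * rng.standard_normal(n)
        cov = np.column_stack([age, sex])

        res_in = cross_validate(X, y, covariates=cov, folds=folds, reps=reps,
                                seed=int(seeds[i]))
        Xr, _ = residualize_in_fold(X, X, cov, cov)
        yr = residualize_in_fold(y[:, None], y[:, None], cov, cov)[0].ravel()
        res_out = cross_validate(Xr, yr, covariates=None, folds=folds, reps=reps,
                                 seed=int(seeds[i]))
        res_none = cross_validate(X, y, covariates=None, folds=folds, reps=reps,
                                  seed=int(seeds[i]))
        devs["in_loop"].append(float(res_in.per_fold_r.mean()))
        devs["out_of_loop"].append(float(res_out.per_fold_r.mean()))
        devs["none"].append(float(res_none.per_fold_r.mean()))
    return {
        "in_loop_max_abs_r": float(np.max(np.abs(devs["in_loop"]))),
        "out_of_loop_mean_abs_r": float(np.mean(np.abs(devs["out_of_loop"]))),
        "confounded_mean_r": float(np.mean(devs["none"])),
        "per_dataset": devs,
    }


# ---------------------------------------------------------------------------
# pipeline determinism
# ---------------------------------------------------------------------------

def _tree_digest(root: Path, pattern: str = "*.tsv") -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(root.glob(pattern))}


def determinism_check(workdir: str | Path, seed: int = 0,
                      config: RunConfig | None = None) -> dict:
    """Run the smoke pipeline twice with one seed; compare table bytes."""
    if config is None:
        config = RunConfig(n_parcels=60, reps=3, n_perm=50, simulate={
            "n_tc1": 8, "n_tc2": 8, "n_rcc": 8, "n_cortex_vertices": 400,
            "n_effect_parcels": 10,
        })
    workdir = Path(workdir)
    digests = []
    for run in ("a", "b"):
        out = workdir / f"run_{run}"
        run_pipeline(config, out, seed=seed)
        digests.append(_tree_digest(out))
    identical = digests[0] == digests[1]
    return {"identical": identical, "n_tables": len(digests[0])}
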