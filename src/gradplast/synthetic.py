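"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the structure of a longitudinal mental-training
study: connectomes drawn from a low-dimensional latent manifold (so the
gradient stage has a recoverable ground truth), a crossover cohort in
which two training cohorts complete the same three modules in different
orders plus an untrained retest control cohort, module-specific parcel
change maps with subject-level random drift, analytic cortical geometries
with known area ratios (so equivolume placement has an exact oracle),
depth-parameterized qT1 fields, and behavior linearly tied to a sparse
subset of brain features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .equivolume import SurfacePair
from .errors import ConfigError, InputShapeError, InputValueError, MeshError
from .io_core import (
    CROSSOVER_ORDER,
    NETWORKS,
    ConnectivityMatrix,
    Parcellation,
    rng_from_seed,
    validate_design,
)

__all__ = [
    "LatentManifold",
    "EffectSpec",
    "make_connectome",
    "make_cohort",
    "make_cortex",
    "AnalyticField",
    "make_qt1_field",
    "sheet_depth_geometry",
    "make_behavior",
    "make_grid_parcellation",
    "make_network_weights",
    "fibonacci_sphere",
    "make_smooth_sphere_maps",
]


# ---------------------------------------------------------------------------
# connectomes from a latent manifold
# ---------------------------------------------------------------------------

@dataclass
class LatentManifold:
    """Latent 3D parcel positions generating a kernel connectome."""

    coords: np.ndarray
    kernel_scale: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise InputValueError("latent coordinates must be finite")
        if self.kernel_scale <= 0:
            raise ConfigError("kernel_scale must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")

    @classmethod
    def random(cls, n_parcels: int, seed: int, kernel_scale: float = 1.0,
               noise_sd: float = 0.0) -> "LatentManifold":
        """Uniform sampling of the unit ball (isotropic, no corner artifacts)."""
        rng = rng_from_seed(seed)
        coords = np.empty((0, 3))
        while coords.shape[0] < n_parcels:
            draw = rng.uniform(-1, 1, size=(2 * n_parcels, 3))
            coords = np.vstack([coords, draw[(draw**2).sum(axis=1) <= 1.0]])
        return cls(coords=coords[:n_parcels], kernel_scale=kernel_scale, noise_sd=noise_sd)


def make_connectome(spec: LatentManifold, seed: int) -> tuple[ConnectivityMatrix, np.ndarray]:
    """Gaussian-kernel connectome over latent positions, plus the positions.

    ``values = exp(-d_ij^2 / kernel_scale)`` with symmetric Gaussian noise
    of scale ``noise_sd``, clipped to [-1, 1], unit diagonal.
    """
    n = spec.coords.shape[0]
    if n < 10:
        raise InputShapeError(f"need at least 10 parcels, got {n}")
    d2 = np.sum((spec.coords[:, None, :] - spec.coords[None, :, :]) ** 2, axis=-1)
    values = np.exp(-d2 / spec.kernel_scale)
    if spec.noise_sd > 0:
        rng = rng_from_seed(seed)
        noise = rng.normal(0.0, spec.noise_sd, size=(n, n))
        values = values + 0.5 * (noise + noise.T)
    values = np.clip(values, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    ids = tuple(f"p{i:03d}" for i in range(n))
    return ConnectivityMatrix(values=values, parcel_ids=ids), spec.coords.copy()


# ---------------------------------------------------------------------------
# crossover cohorts with planted module effects
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Planted per-module parcel change maps plus variance components.

    ``effect_maps[tm]`` is the mean per-interval change added whenever a
    subject completes module ``tm``; ``subject_sd`` scales a per-subject,
    per-parcel drift constant across that subject's intervals;
    ``residual_sd`` scales independent interval-level noise. Untrained
    intervals add no effect map.
    """

    effect_maps: dict[str, np.ndarray] = field(default_factory=dict)
    subject_sd: float = 0.0
    residual_sd: float = 0.0
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0

    def __post_init__(self):
        self.effect_maps = {k: np.asarray(v, dtype=float) for k, v in self.effect_maps.items()}
        for tm, m in self.effect_maps.items():
            if not np.isfinite(m).all():
                raise InputValueError(f"effect map for {tm!r} has non-finite entries")
        if self.subject_sd < 0 or self.residual_sd < 0 or self.baseline_sd < 0:
            raise ConfigError("variance component scales must be nonnegative")

    @classmethod
    def null(cls, n_parcels: int, subject_sd: float = 0.0,
             residual_sd: float = 1.0) -> "EffectSpec":
        zero = np.zeros(n_parcels)
        return cls(effect_maps={tm: zero.copy() for tm in ("Presence", "Affect", "Perspective")},
                   subject_sd=subject_sd, residual_sd=residual_sd)


def make_cohort(
    n_tc1: int,
    n_tc2: int,
    n_rcc: int,
    effects: EffectSpec,
    n_parcels: int,
    seed: int,
    n_tc3: int = 0,
    age_range: tuple[float, float] = (20.0, 55.0),
    p_female: float = 0.59,
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Simulate a crossover longitudinal cohort and per-scan metric maps.

    Returns a validated design table (subjects x 4 timepoints; TC3 subjects
    stop after T1) and a map ``{(subject_id, timepoint): parcel vector}``
    built forward in time:

        map(T_{k+1}) = map(T_k) + effect_map(module of that interval)
                       + subject_drift + interval_noise

    Ages are uniform on ``age_range`` and sex is Bernoulli (1 = female,
    default rate 0.59), used only as nuisance structure.
    """
    if min(n_tc1, n_tc2, n_rcc, n_tc3) < 0:
        raise ConfigError("cohort sizes must be nonnegative")
    rng = rng_from_seed(seed)
    rows = []
    maps: dict[tuple[str, str], np.ndarray] = {}
    cohort_sizes = [("TC1", n_tc1), ("TC2", n_tc2), ("RCC", n_rcc), ("TC3", n_tc3)]
    zero = np.zeros(n_parcels)
    idx = 0
    for cohort, size in cohort_sizes:
        order = CROSSOVER_ORDER[cohort]
        n_tp = len(order) + 1 if cohort == "TC3" else 4
        for _ in range(size):
            sid = f"s{idx:04d}"
            idx += 1
            age = rng.uniform(*age_range)
            sex = int(rng.random() < p_female)
            drift = (effects.subject_sd * rng.standard_normal(n_parcels)
                     if effects.subject_sd > 0 else zero)
            current = effects.baseline_mean + (
                effects.baseline_sd * rng.standard_normal(n_parcels)
                if effects.baseline_sd > 0 else zero.copy()
            )
            current = np.asarray(current, dtype=float) + np.zeros(n_parcels)
            for k in range(n_tp):
                tp = f"T{k}"
                if k > 0:
                    tm = order[k - 1] if k - 1 < len(order) else "None"
                    eff = effects.effect_maps.get(tm, zero) if tm != "None" else zero
                    noise = (effects.residual_sd * rng.standard_normal(n_parcels)
                             if effects.residual_sd > 0 else zero)
                    current = current + eff + drift + noise
                else:
                    tm = "None"
                rows.append((sid, cohort, tp, tm, age, sex, k))
                maps[(sid, tp)] = current.copy()
    design = pd.DataFrame(
        rows, columns=["subject_id", "cohort", "timepoint", "tm", "age", "sex", "interval_index"]
    )
    return validate_design(design), maps


# ---------------------------------------------------------------------------
# analytic cortical geometries
# ---------------------------------------------------------------------------

def _grid_faces(nu: int, nv: int) -> np.ndarray:
    """Triangulate a regular (nu x nv) vertex grid."""
    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a = i * nv + j
            b = a + 1
            c = a + nv
            d = c + 1
            faces.append((a, b, c))
            faces.append((b, d, c))
    return np.asarray(faces, dtype=int)


def make_cortex(
    shape: str = "sheet",
    n_vertices: int = 400,
    thickness: float = 3.0,
    area_ratio: float = 2.0,
    amplitude: float = 0.0,
    extent: float = 20.0,
    radii: tuple[float, float] = (30.0, 33.0),
    seed: int | None = None,
) -> SurfacePair:
    """Build a paired white/pial mesh with known analytic geometry.

    Shapes (all in mm, 1-1 vertex correspondence, identical topology):

    - ``"sheet"`` / ``"sinusoidal_sheet"``: a square grid of side
      ``extent``; the white surface is flat (or sinusoidally undulating
      with the given ``amplitude``) and the pial surface is offset by
      ``thickness`` along the vertex normal.
    - ``"wedge"``: a flat white rectangle whose pial counterpart is scaled
      in-plane so that every cortical column's outer/inner area ratio
      equals ``area_ratio`` exactly; cross-sectional area varies linearly
      with depth, making the equivolumetric placement analytically exact.
    - ``"sphere_patch"``: a patch of concentric spheres at
      ``radii = (white, pial)``.
    """
    m = max(int(round(np.sqrt(n_vertices))), 3)
    u = np.linspace(0.0, extent, m)
    faces = _grid_faces(m, m)
    if shape in ("sheet", "sinusoidal_sheet"):
        xx, yy = np.meshgrid(u, u, indexing="ij")
        if shape == "sinusoidal_sheet" and amplitude != 0:
            zz = amplitude * np.sin(2 * np.pi * xx / extent) * np.cos(2 * np.pi * yy / extent)
        else:
            zz = np.zeros_like(xx)
        white = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        # vertex normals from the analytic surface gradient
        if shape == "sinusoidal_sheet" and amplitude != 0:
            dzdx = (amplitude * 2 * np.pi / extent) * np.cos(2 * np.pi * xx / extent) \
                * np.cos(2 * np.pi * yy / extent)
            dzdy = -(amplitude * 2 * np.pi / extent) * np.sin(2 * np.pi * xx / extent) \
                * np.sin(2 * np.pi * yy / extent)
            normals = np.column_stack([-dzdx.ravel(), -dzdy.ravel(), np.ones(m * m)])
            normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        else:
            normals = np.tile([0.0, 0.0, 1.0], (m * m, 1))
        pial = white + thickness * normals
    elif shape == "wedge":
        if area_ratio <= 0:
            raise InputValueError("area_ratio must be positive")
        xx, yy = np.meshgrid(u, u, indexing="ij")
        white = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(m * m)])
        # scale one in-plane axis by area_ratio about the patch center, so the
        # cross-sectional area varies *linearly* along each (slanted) column
        c = extent / 2.0
        pial = np.column_stack(
            [xx.ravel(), c + area_ratio * (yy.ravel() - c), np.full(m * m, thickness)]
        )
    elif shape == "sphere_patch":
        r_white, r_pial = radii
        theta = np.linspace(0.4, 1.1, m)  # polar angle, away from the pole
        phi = np.linspace(0.0, 0.7, m)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        unit = np.column_stack(
            [np.sin(tt.ravel()) * np.cos(pp.ravel()),
             np.sin(tt.ravel()) * np.sin(pp.ravel()),
             np.cos(tt.ravel())]
        )
        white = r_white * unit
        pial = r_pial * unit
    else:
        raise InputValueError(f"unknown cortex shape {shape!r}")
    sp = SurfacePair(white_vertices=white, pial_vertices=pial, faces=faces)
    from .equivolume import triangle_areas

    if np.any(triangle_areas(white, faces) <= 0) or np.any(triangle_areas(pial, faces) <= 0):
        raise MeshError("degenerate triangles in generated cortex")
    return sp


def make_grid_parcellation(n_vertices: int, n_parcels: int) -> Parcellation:
    """Split a vertex range into contiguous, equally sized parcels."""
    labels = np.minimum(
        (np.arange(n_vertices) * n_parcels) // n_vertices + 1, n_parcels
    )
    ids = tuple(f"p{i:03d}" for i in range(n_parcels))
    return Parcellation(vertex_labels=labels, parcel_ids=ids)


# ---------------------------------------------------------------------------
# analytic qT1 fields
# ---------------------------------------------------------------------------

class AnalyticField:
    """Scalar field defined by a callable on world coordinates (mm -> ms)."""

    def __init__(self, fn):
        self._fn = fn

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return np.asarray(self._fn(points), dtype=float)


def sheet_depth_geometry(thickness: float, region_split_x: float | None = None):
    """Map sheet-cortex positions to (depth_fraction, region).

    Depth fraction is 0 at the pial surface (z = thickness) and 1 at the
    white surface (z = 0). An optional x threshold splits two regions.
    """

    def geometry(points: np.ndarray):
        depth = 1.0 - points[:, 2] / thickness
        if region_split_x is None:
            region = np.zeros(len(points), dtype=int)
        else:
            region = (points[:, 0] >= region_split_x).astype(int)
        return depth, region

    return geometry


def make_qt1_field(
    profile,
    geometry,
    grid_shape: tuple[int, int, int] = (32, 32, 16),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    spacing: tuple[float, float, float] = (1.0, 1.0, 0.25),
) -> tuple[AnalyticField, nib.Nifti1Image]:
    """Analytic qT1 field plus a rasterized NIfTI volume agreeing at voxel centers.

    ``profile(depth_fraction, region) -> qT1 (ms)`` must be finite on
    [0, 1]; ``geometry(points) -> (depth_fraction, region)`` maps world
    coordinates to the profile's arguments.
    """
    probe = np.asarray(profile(np.array([0.0, 0.5, 1.0]), np.zeros(3, dtype=int)), dtype=float)
    if not np.isfinite(probe).all():
        raise InputValueError("profile must be finite on [0, 1]")

    def fn(points):
        depth, region = geometry(points)
        return profile(np.asarray(depth, dtype=float), np.asarray(region))

    analytic = AnalyticField(fn)
    nx, ny, nz = grid_shape
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    affine[:3, 3] = origin
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = vox * np.asarray(spacing) + np.asarray(origin)
    data = analytic.evaluate(world).reshape(grid_shape)
    return analytic, nib.Nifti1Image(data.astype(np.float64), affine)


# ---------------------------------------------------------------------------
# behavior, networks, spheres
# ---------------------------------------------------------------------------

def make_behavior(
    feature_table: np.ndarray, true_weights: np.ndarray, noise_sd: float, seed: int
) -> np.ndarray:
    """Behavior change linearly tied to brain features: ``y = X w + eps``."""
    X = np.asarray(feature_table, dtype=float)
    w = np.asarray(true_weights, dtype=float)
    if w.shape[0] != X.shape[1]:
        raise InputShapeError(f"weights length {w.shape[0]} != n_features {X.shape[1]}")
    y = X @ w
    if noise_sd > 0:
        y = y + rng_from_seed(seed).normal(0.0, noise_sd, size=X.shape[0])
    return y


def make_network_weights(n_parcels: int, seed: int, parcels_per_network: int = 40):
    """Random binary network masks over parcels, one per a-priori network."""
    rng = rng_from_seed(seed)
    weights = {}
    for name in NETWORKS:
        members = rng.choice(n_parcels, size=min(parcels_per_network, n_parcels), replace=False)
        w = np.zeros(n_parcels)
        w[members] = 1.0
        weights[name] = w
    from .io_core import NetworkWeights

    return NetworkWeights(weights=weights)


def make_reference_embedding(
    n_parcels: int, k: int = 10, seed: int = 20, density: float = 0.10,
    embedding_alpha: float = 0.5,
):
    """Synthetic group-level reference embedding for Procrustes alignment.

    A deterministic stand-in for a population template embedding: a fixed
    latent-manifold connectome (noise-free, fixed seed) run through the
    standard gradient pipeline. Any user-supplied embedding may be used
    instead; this one exists so alignment is exercisable with no external
    data.
    """
    from .gradients import diffusion_embedding, normalized_angle, threshold_rows

    manifold = LatentManifold.random(n_parcels, seed=seed, kernel_scale=1.0, noise_sd=0.0)
    cm, _ = make_connectome(manifold, seed=seed)
    emb = diffusion_embedding(
        normalized_angle(threshold_rows(cm, density=density)),
        embedding_alpha=embedding_alpha, k=k,
    )
    emb.alignment_ref = None
    return emb


def fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_smooth_sphere_maps(
    n_parcels: int, n_maps: int, seed: int, smoothing: float = 0.6
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially autocorrelated maps on sphere parcels (for spin-test nulls).

    White noise over parcels is convolved with a Gaussian kernel in chordal
    distance (``smoothing`` is the kernel length scale on the unit sphere),
    then standardized per map. Returns (centroids, maps[n_maps, n_parcels]);
    maps generated this way are mutually independent but share the same
    spatial autocorrelation.
    """
    coords = fibonacci_sphere(n_parcels)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    K = np.exp(-d2 / (2 * smoothing**2))
    rng = rng_from_seed(seed)
    raw = rng.standard_normal((n_maps, n_parcels)) @ K.T
    raw = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)
    return coords, raw
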