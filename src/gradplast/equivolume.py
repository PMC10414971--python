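"""Equivolumetric laminar surfaces and cortical depth profiling.

Cortical folding compresses deep layers in sulci and stretches them at
gyral crowns, so surfaces placed at fixed *distance* fractions between pial
and white do not sample homologous laminae. The equivolumetric model
instead places each intracortical surface so that a fixed fraction of the
local cortical *volume* lies beneath it: for a cortical column whose
cross-sectional area varies linearly from the inner (white) area ``A_in``
to the outer (pial) area ``A_out``, the distance fraction of the surface
enclosing volume fraction ``alpha`` is

    rho = (-A_in + sqrt(alpha * A_out**2 + (1 - alpha) * A_in**2)) / (A_out - A_in)

with the analytic limit ``rho = alpha`` when the areas are equal (flat
cortex). A quantitative T1 field sampled on the resulting stack of 12
surfaces yields parcel-by-depth profiles; depths 1-4, 5-8 and 9-12 are
grouped into superficial, middle and deep compartments (depth 1 is
pial-adjacent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy.ndimage import map_coordinates

from .errors import (
    InputShapeError,
    InputValueError,
    MeshError,
    NumericalError,
    ParcellationError,
    SamplingError,
)
from .io_core import Parcellation, logger

COMPARTMENTS = {"superficial": (1, 4), "middle": (5, 8), "deep": (9, 12)}


@dataclass
class SurfacePair:
    """Corresponding white and pial triangle meshes (mm) with shared topology."""

    white_vertices: np.ndarray
    pial_vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.white_vertices = np.asarray(self.white_vertices, dtype=float)
        self.pial_vertices = np.asarray(self.pial_vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.white_vertices.shape != self.pial_vertices.shape:
            raise InputShapeError("white and pial vertex arrays differ in shape")
        if not (np.isfinite(self.white_vertices).all() and np.isfinite(self.pial_vertices).all()):
            raise MeshError("non-finite vertex coordinates")

    @property
    def n_vertices(self) -> int:
        return self.white_vertices.shape[0]


@dataclass
class LaminarStack:
    """Intracortical surfaces ordered superficial (pial-adjacent) to deep.

    ``surfaces[d - 1]`` is depth ``d``; ``rho`` holds each surface's
    per-vertex distance fraction measured from the white surface toward
    pial, and ``volume_fractions`` the corresponding volume fractions
    (also measured from white).
    """

    surfaces: np.ndarray  # (n_surfaces, n_vertices, 3)
    rho: np.ndarray  # (n_surfaces, n_vertices)
    volume_fractions: np.ndarray  # (n_surfaces,)
    faces: np.ndarray
    orientation: str = "superficial_to_deep"

    @property
    def n_surfaces(self) -> int:
        return self.surfaces.shape[0]


@dataclass
class DepthProfileTable:
    """Parcel-by-depth qT1 profile matrix (ms) with per-parcel flags."""

    values: np.ndarray  # (n_parcels, n_depths)
    parcel_ids: tuple[str, ...]
    low_confidence: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.parcel_ids = tuple(str(p) for p in self.parcel_ids)
        if self.low_confidence is None:
            self.low_confidence = np.zeros(self.values.shape[0], dtype=bool)

    @property
    def n_depths(self) -> int:
        return self.values.shape[1]


def load_surface_pair(white_path: str | Path, pial_path: str | Path) -> SurfacePair:
    """Load corresponding white/pial meshes (PLY/OFF/OBJ via trimesh).

    The two files must triangulate the same topology with 1-1 vertex
    correspondence (the linked-vertex convention).
    """
    white = trimesh.load_mesh(str(white_path), process=False)
    pial = trimesh.load_mesh(str(pial_path), process=False)
    if white.faces.shape != pial.faces.shape or not np.array_equal(white.faces, pial.faces):
        raise MeshError("white and pial meshes do not share triangle topology")
    return SurfacePair(white_vertices=np.asarray(white.vertices, dtype=float),
                       pial_vertices=np.asarray(pial.vertices, dtype=float),
                       faces=np.asarray(white.faces, dtype=int))


def save_surface(vertices: np.ndarray, faces: np.ndarray, path: str | Path) -> None:
    """Write one triangulated surface (format from the file extension)."""
    trimesh.Trimesh(vertices=vertices, faces=faces, process=False).export(str(path))


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=int)
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex surface area: one third of each incident triangle's area.

    The per-vertex areas sum exactly to the total mesh area.
    """
    tri = triangle_areas(vertices, faces)
    if np.any(tri <= 0):
        raise MeshError(f"{int(np.sum(tri <= 0))} degenerate (zero-area) triangles")
    out = np.zeros(len(vertices))
    np.add.at(out, np.asarray(faces, dtype=int).ravel(), np.repeat(tri / 3.0, 3))
    return out


def equivolume_fraction(a_in, a_out, alpha) -> np.ndarray | float:
    """Distance fraction enclosing volume fraction ``alpha`` of a column.

    ``a_in`` / ``a_out`` are the inner (white) and outer (pial) surface
    areas of the column; ``alpha`` is measured from the white surface.
    Vectorized over any broadcastable combination; near-equal areas take
    the analytic limit ``rho = alpha``.
    """
    a_in = np.asarray(a_in, dtype=float)
    a_out = np.asarray(a_out, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(a_in <= 0) or np.any(a_out <= 0):
        raise InputValueError("surface areas must be positive")
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise InputValueError("alpha must lie in [0, 1]")
    diff = a_out - a_in
    eps = 1e-12 * np.maximum(a_in, a_out)
    flat = np.abs(diff) < eps
    safe_diff = np.where(flat, 1.0, diff)
    rho = (-a_in + np.sqrt(alpha * a_out**2 + (1.0 - alpha) * a_in**2)) / safe_diff
    rho = np.where(flat, alpha, rho)
    rho = np.clip(rho, 0.0, 1.0)
    return rho if rho.ndim else float(rho)


def build_laminar_stack(
    sp: SurfacePair, n_surfaces: int = 12, fraction_mode: str = "interior"
) -> LaminarStack:
    """Place equivolumetric surfaces between the white and pial meshes.

    Volume fractions are ``i / (n + 1)`` for ``i = 1..n`` (strictly
    intracortical, ``fraction_mode="interior"``) or ``(i - 0.5) / n``
    (``"centered"``). Each vertex of surface ``i`` sits on the straight
    segment joining its white and pial counterparts at the equivolumetric
    distance fraction computed from the local white/pial vertex areas.
    """
    a_in = vertex_areas(sp.white_vertices, sp.faces)
    a_out = vertex_areas(sp.pial_vertices, sp.faces)
    if fraction_mode == "interior":
        fracs = np.arange(1, n_surfaces + 1) / (n_surfaces + 1)
    elif fraction_mode == "centered":
        fracs = (np.arange(1, n_surfaces + 1) - 0.5) / n_surfaces
    else:
        raise InputValueError(f"unknown fraction_mode {fraction_mode!r}")
    # superficial first: largest volume-from-white fraction first
    fracs = fracs[::-1].copy()
    rho = equivolume_fraction(a_in[None, :], a_out[None, :], fracs[:, None])
    seg = sp.pial_vertices - sp.white_vertices
    surfaces = sp.white_vertices[None, :, :] + rho[:, :, None] * seg[None, :, :]
    non_monotone = int(np.sum(np.diff(rho, axis=0) >= 0))
    if non_monotone:
        logger.warning("laminar stack: %d non-monotone vertex placements", non_monotone)
    return LaminarStack(
        surfaces=surfaces, rho=rho, volume_fractions=fracs, faces=sp.faces.copy()
    )


def sample_field(stack: LaminarStack, fieldobj) -> np.ndarray:
    """Sample a qT1 field at every vertex of every laminar surface.

    ``fieldobj`` may be an analytic field (any object with an
    ``evaluate(points)`` method, evaluated exactly), a nibabel spatial
    image, or a path to a NIfTI file (trilinear interpolation in world
    coordinates). Out-of-bounds vertices come back NaN; more than 5%
    missing raises :class:`SamplingError`. Returns an
    ``(n_vertices, n_surfaces)`` array with columns ordered by depth
    (column 0 = most superficial).
    """
    pts = stack.surfaces.reshape(-1, 3)
    if hasattr(fieldobj, "evaluate"):
        vals = np.asarray(fieldobj.evaluate(pts), dtype=float)
    else:
        img = nib.load(str(fieldobj)) if isinstance(fieldobj, (str, Path)) else fieldobj
        data = np.asanyarray(img.dataobj, dtype=float)
        inv = np.linalg.inv(img.affine)
        vox = (pts @ inv[:3, :3].T) + inv[:3, 3]
        vals = map_coordinates(data, vox.T, order=1, mode="constant", cval=np.nan)
        inside = np.all((vox >= -0.5) & (vox <= np.array(data.shape) - 0.5), axis=1)
        vals[~inside] = np.nan
    vals = vals.reshape(stack.n_surfaces, -1).T
    frac_missing = np.isnan(vals).mean()
    if frac_missing > 0.05:
        raise SamplingError(f"{frac_missing:.1%} of samples out of bounds (limit 5%)")
    if frac_missing > 0:
        logger.info("sample_field: %.2f%% samples missing", 100 * frac_missing)
    return vals


def parcel_profiles(samples: np.ndarray, parcellation: Parcellation) -> DepthProfileTable:
    """Average vertex-wise depth samples within each parcel.

    Missing samples are excluded pairwise; parcels with fewer than 10
    valid vertices (or none at all) are flagged low-confidence.
    """
    samples = np.asarray(samples, dtype=float)
    labels = parcellation.vertex_labels
    if labels.shape[0] != samples.shape[0]:
        raise InputShapeError(
            f"{labels.shape[0]} labels for {samples.shape[0]} vertex samples"
        )
    if not np.any(labels > 0):
        raise ParcellationError("all vertices unassigned")
    n_parcels = len(parcellation.parcel_ids)
    values = np.full((n_parcels, samples.shape[1]), np.nan)
    low_conf = np.zeros(n_parcels, dtype=bool)
    for p in range(n_parcels):
        rows = samples[labels == p + 1]
        valid = ~np.isnan(rows)
        n_valid = valid.all(axis=1).sum() if rows.size else 0
        if rows.size:
            with np.errstate(invalid="ignore"):
                counts = valid.sum(axis=0)
                sums = np.nansum(rows, axis=0)
                values[p] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        if n_valid < 10:
            low_conf[p] = True
    if low_conf.any():
        logger.info("parcel_profiles: %d low-confidence parcels", int(low_conf.sum()))
    return DepthProfileTable(
        values=values, parcel_ids=parcellation.parcel_ids, low_confidence=low_conf
    )


def depth_zscore(t: DepthProfileTable) -> DepthProfileTable:
    """Standardize each depth column across parcels (population denominator)."""
    v = t.values
    if v.shape[0] < 2:
        raise InputShapeError("z-scoring needs at least 2 parcels")
    mean = np.nanmean(v, axis=0)
    sd = np.nanstd(v, axis=0)
    if np.any(sd == 0):
        raise NumericalError("zero-variance depth column; cannot z-score")
    return DepthProfileTable(
        values=(v - mean) / sd, parcel_ids=t.parcel_ids, low_confidence=t.low_confidence.copy()
    )


def compartment_means(t: DepthProfileTable) -> dict[str, np.ndarray]:
    """Mean profile over the superficial (1-4), middle (5-8), deep (9-12) depths."""
    if t.n_depths != 12:
        raise InputShapeError(f"compartment grouping expects 12 depths, got {t.n_depths}")
    out = {}
    for name, (lo, hi) in COMPARTMENTS.items():
        out[name] = t.values[:, lo - 1 : hi].mean(axis=1)
    return out
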