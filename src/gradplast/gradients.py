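"""Functional-gradient stage.

Connectivity rows are proportionally thresholded (top 10% retained by
default), converted to a normalized-angle affinity, and embedded with a
diffusion map. Individual embeddings are Procrustes-rotated to a reference,
and the first three aligned gradients are condensed into per-parcel
eccentricity — the Euclidean distance to the centroid of the 3D gradient
space, a scalar marker of functional integration (low) vs segregation
(high).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

from .errors import (
    GraphError,
    InputShapeError,
    InputValueError,
    NumericalError,
    TieError,
)
from .io_core import ConnectivityMatrix, NetworkWeights

__all__ = [
    "AffinityMatrix",
    "GradientEmbedding",
    "EccentricityMap",
    "threshold_rows",
    "normalized_angle",
    "diffusion_embedding",
    "procrustes_align",
    "eccentricity",
    "network_summary",
]


@dataclass
class AffinityMatrix:
    """Symmetric similarity matrix in [0, 1] with unit diagonal."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InputShapeError(f"affinity must be square, got {v.shape}")
        if np.abs(v - v.T).max() > 1e-10:
            raise InputValueError("affinity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise InputValueError("affinity entries must lie in [0, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = np.clip(v, 0.0, 1.0)


@dataclass
class GradientEmbedding:
    """Diffusion-map component scores with eigenvalues and provenance.

    ``scores[:, :3]`` are the gradients G1-G3. ``params`` records the
    density parameter (alpha), diffusion time and component count;
    ``alignment_ref`` names the reference the embedding was rotated to,
    if any.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    params: dict = field(default_factory=dict)
    alignment_ref: str | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise InputValueError("eigenvalues must be nonincreasing")

    @property
    def n_parcels(self) -> int:
        return self.scores.shape[0]

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class EccentricityMap:
    """Per-parcel distance to the center of the G1-G2-G3 space."""

    values: np.ndarray
    center_used: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise InputValueError("eccentricities must be finite and nonnegative")


def threshold_rows(
    m: ConnectivityMatrix | np.ndarray,
    density: float = 0.10,
    tie_policy: str = "stable",
) -> np.ndarray:
    """Proportional row thresholding: keep each row's strongest connections.

    Per row, the ``ceil(density * (n - 1))`` largest off-diagonal entries
    survive and all others are zeroed; the diagonal is zeroed. The output
    is generally asymmetric. Boundary ties are broken deterministically by
    (value descending, column index ascending); ``tie_policy="error"``
    raises :class:`TieError` when the boundary is tied instead.
    """
    values = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    n = values.shape[0]
    if not (0 < density <= 1):
        raise InputValueError(f"density must lie in (0, 1], got {density}")
    keep = int(np.ceil(density * (n - 1)))
    out = np.zeros_like(values)
    cols = np.arange(n)
    for i in range(n):
        row = values[i].copy()
        off = cols != i
        # sort off-diagonal by (value desc, index asc)
        idx = cols[off]
        order = np.lexsort((idx, -row[off]))
        kept = idx[order[:keep]]
        if tie_policy == "error" and keep < idx.size:
            boundary = row[idx[order[keep - 1]]]
            next_val = row[idx[order[keep]]]
            if boundary == next_val:
                raise TieError(f"row {i}: tied values at the threshold boundary")
        out[i, kept] = row[kept]
    return out


def normalized_angle(thr: np.ndarray) -> AffinityMatrix:
    """Normalized-angle affinity between connectivity rows.

    ``a_ij = 1 - arccos(cos_sim(row_i, row_j)) / pi``, bounded in [0, 1]:
    1 for identical rows, 0.5 for orthogonal rows, 0 for anti-parallel.
    """
    thr = np.asarray(thr, dtype=float)
    norms = np.linalg.norm(thr, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise InputValueError(f"row {bad} has zero norm; cannot form angles")
    unit = thr / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    ang = 1.0 - np.arccos(cos) / np.pi
    ang = 0.5 * (ang + ang.T)
    np.fill_diagonal(ang, 1.0)
    return AffinityMatrix(values=ang)


def diffusion_embedding(
    a: AffinityMatrix,
    embedding_alpha: float = 0.5,
    diffusion_time: float = 0.0,
    k: int = 10,
) -> GradientEmbedding:
    """Diffusion-map embedding of an affinity matrix.

    The affinity is density-normalized with exponent ``embedding_alpha``
    (0: maximal density influence, 1: none), row-normalized into a Markov
    transition operator, and eigendecomposed via its symmetric conjugate
    for stability. The trivial constant eigenvector is dropped. At
    ``diffusion_time == 0`` the multiscale convention scales component i by
    ``lambda_i / (1 - lambda_i)``; for t > 0 by ``lambda_i ** t``.
    Components are ordered by eigenvalue and
    ``variance_explained_i = lambda_i**2 / sum(lambda**2)`` over the
    nontrivial spectrum.
    """
    A = a.values
    n = A.shape[0]
    if k >= n:
        raise InputShapeError(f"k={k} must be < n={n}")
    n_comp, _ = scipy.sparse.csgraph.connected_components(A > 0, directed=False)
    if n_comp > 1:
        raise GraphError(f"affinity graph has {n_comp} connected components")

    d = A.sum(axis=1)
    W = A / np.outer(d**embedding_alpha, d**embedding_alpha)
    dw = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dw)
    S = W * np.outer(inv_sqrt, inv_sqrt)
    S = 0.5 * (S + S.T)
    lam, V = scipy.linalg.eigh(S)
    lam, V = lam[::-1], V[:, ::-1]

    if lam[0] > 1 + 1e-8:
        raise NumericalError(f"leading eigenvalue {lam[0]:.6f} exceeds 1")
    lam = np.minimum(lam, 1.0)
    # back-transform to unit-norm right eigenvectors of the transition
    # operator, then rescale so the trivial eigenvector is constant 1
    psi = V * inv_sqrt[:, None]
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    psi = psi / psi[:, [0]]

    lam_nt = lam[1:]
    if np.any(lam_nt >= 1 - 1e-10):
        raise NumericalError("nontrivial eigenvalue at 1: disconnected or degenerate operator")
    if diffusion_time == 0:
        scale = lam_nt / (1.0 - lam_nt)
    else:
        scale = np.sign(lam_nt) * np.abs(lam_nt) ** diffusion_time
    scores = psi[:, 1:] * scale[None, :]

    var_exp = lam_nt**2 / np.sum(lam_nt**2)
    return GradientEmbedding(
        scores=scores[:, :k],
        eigenvalues=lam_nt[:k],
        variance_explained=var_exp[:k],
        params={"embedding_alpha": embedding_alpha, "diffusion_time": diffusion_time, "k": k},
    )


def procrustes_align(
    source: GradientEmbedding,
    reference: GradientEmbedding,
    n_components: int | None = None,
    ref_name: str = "reference",
) -> GradientEmbedding:
    """Rotate a source embedding onto a reference (orthogonal Procrustes).

    A single orthogonal transform (rotation/reflection; no scaling or
    translation) minimizing the Frobenius distance between score matrices
    is applied to the first ``n_components`` source components. Eigenvalues
    are unchanged; pairwise distances between parcels are preserved.
    """
    if source.n_parcels != reference.n_parcels:
        raise InputShapeError(
            f"parcel mismatch: {source.n_parcels} vs {reference.n_parcels}"
        )
    if n_components is None:
        n_components = min(source.k, reference.k)
    if n_components > source.k or n_components > reference.k:
        raise InputShapeError("n_components exceeds available components")
    S = source.scores[:, :n_components]
    R = reference.scores[:, :n_components]
    Q, _ = scipy.linalg.orthogonal_procrustes(S, R)
    return GradientEmbedding(
        scores=S @ Q,
        eigenvalues=source.eigenvalues[:n_components],
        variance_explained=source.variance_explained[:n_components],
        params=dict(source.params),
        alignment_ref=ref_name,
    )


def eccentricity(e: GradientEmbedding, center: str = "individual_centroid") -> EccentricityMap:
    """Per-parcel Euclidean distance to the center of G1-G2-G3 space.

    ``center="individual_centroid"`` (default) uses the mean of the first
    three gradient scores over parcels; ``center="origin"`` uses the origin
    of the aligned space.
    """
    if e.k < 3:
        raise InputShapeError(f"eccentricity needs >= 3 components, embedding has {e.k}")
    g = e.scores[:, :3]
    if center == "individual_centroid":
        c = g.mean(axis=0)
    elif center == "origin":
        c = np.zeros(3)
    else:
        raise InputValueError(f"unknown center mode {center!r}")
    return EccentricityMap(values=np.linalg.norm(g - c, axis=1), center_used=c)


def network_summary(values: np.ndarray, w: NetworkWeights) -> dict[str, float]:
    """Weighted mean of a per-parcel map within each named network."""
    values = np.asarray(values, dtype=float)
    out = {}
    for name in w.names:
        wv = w[name]
        if wv.shape[0] != values.shape[0]:
            raise InputShapeError(
                f"network {name!r}: weight length {wv.shape[0]} != map length {values.shape[0]}"
            )
        total = wv.sum()
        if total == 0:
            raise InputValueError(f"network {name!r} has zero total weight")
        out[name] = float(np.dot(wv, values) / total)
    return out
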