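import numpy as np
import pytest
import scipy.spatial
import scipy.stats

from gradplast.errors import GraphError, InputShapeError, InputValueError, TieError
from gradplast.gradients import (
    AffinityMatrix,
    GradientEmbedding,
    diffusion_embedding,
    eccentricity,
    network_summary,
    normalized_angle,
    procrustes_align,
    threshold_rows,
)
from gradplast.io_core import NetworkWeights


def brute_force_threshold(values, density):
    """Independent oracle: per-row sort by (value desc, index asc), keep top."""
    n = values.shape[0]
    keep = int(np.ceil(density * (n - 1)))
    out = np.zeros_like(values)
    for i in range(n):
        pairs = sorted(((values[i, j], j) for j in range(n) if j != i),
                       key=lambda vj: (-vj[0], vj[1]))
        for v, j in pairs[:keep]:
            out[i, j] = v
    return out


class TestThresholdRows:
    def test_density_one_keeps_all_off_diagonal(self, rng):
        m = rng.uniform(size=(8, 8))
        m = 0.5 * (m + m.T)
        out = threshold_rows(m, density=1.0)
        expected = m.copy()
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_array_equal(out, expected)

    def test_single_survivor_equals_row_max(self, rng):
        m = rng.uniform(size=(4, 4))
        m = 0.5 * (m + m.T)
        out = threshold_rows(m, density=0.34)  # ceil(0.34 * 3) = 2? no: 1.02 -> 2
        keep = int(np.ceil(0.34 * 3))
        for i in range(4):
            assert np.count_nonzero(out[i]) == keep

    @pytest.mark.parametrize("density", [0.1, 0.34, 0.5, 0.9])
    def test_matches_brute_force_oracle(self, density, rng):
        for _ in range(5):
            m = rng.uniform(size=(17, 17))
            m = 0.5 * (m + m.T)
            np.testing.assert_array_equal(
                threshold_rows(m, density=density), brute_force_threshold(m, density)
            )

    def test_tied_boundary_resolved_by_index(self):
        # row 0: all off-diagonal values tied; stable policy keeps lowest indices
        m = np.full((5, 5), 0.5)
        out = threshold_rows(m, density=0.5)  # keep ceil(0.5*4) = 2
        assert np.flatnonzero(out[0]).tolist() == [1, 2]
        with pytest.raises(TieError):
            threshold_rows(m, density=0.5, tie_policy="error")

    def test_retained_values_unchanged(self, rng):
        m = rng.uniform(size=(12, 12))
        m = 0.5 * (m + m.T)
        out = threshold_rows(m, density=0.25)
        nz = out != 0
        np.testing.assert_array_equal(out[nz], m[nz])

    def test_invalid_density_rejected(self):
        with pytest.raises(InputValueError):
            threshold_rows(np.eye(4), density=0.0)


class TestNormalizedAngle:
    def test_identical_orthogonal_antiparallel_rows(self):
        thr = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert normalized_angle(thr).values[0, 1] == pytest.approx(1.0)
        thr = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert normalized_angle(thr).values[0, 1] == pytest.approx(0.5)
        thr = np.array([[1.0, 0.0], [-1.0, 0.0]])
        assert normalized_angle(thr).values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_norm_row_rejected(self):
        with pytest.raises(InputValueError):
            normalized_angle(np.array([[1.0, 0.0], [0.0, 0.0]]))

    def test_output_is_valid_affinity(self, rng):
        thr = rng.uniform(size=(10, 10))
        a = normalized_angle(thr)
        assert np.abs(a.values - a.values.T).max() == 0
        assert a.values.min() >= 0 and a.values.max() <= 1
        np.testing.assert_allclose(np.diag(a.values), 1.0)


class TestDiffusionEmbedding:
    def test_two_block_affinity_first_gradient_separates_blocks(self):
        n = 20
        a = np.full((n, n), 0.1)
        a[:10, :10] = 0.9
        a[10:, 10:] = 0.9
        np.fill_diagonal(a, 1.0)
        emb = diffusion_embedding(AffinityMatrix(a), k=5)
        g1 = emb.scores[:, 0]
        assert len(np.unique(np.sign(g1[:10]))) == 1
        assert np.sign(g1[0]) != np.sign(g1[10])

    def test_ring_affinity_gives_degenerate_fourier_pair(self):
        # circulant nearest-neighbour ring: leading nontrivial eigenvectors
        # are a sine/cosine pair with equal eigenvalues
        n = 24
        a = np.eye(n)
        idx = np.arange(n)
        a[idx, (idx + 1) % n] = 1.0
        a[idx, (idx - 1) % n] = 1.0
        emb = diffusion_embedding(AffinityMatrix(a), k=4)
        assert emb.eigenvalues[0] == pytest.approx(emb.eigenvalues[1], abs=1e-10)
        theta = 2 * np.pi * idx / n
        basis = np.column_stack([np.cos(theta), np.sin(theta)])
        proj = basis @ np.linalg.lstsq(basis, emb.scores[:, :2], rcond=None)[0]
        np.testing.assert_allclose(proj, emb.scores[:, :2], atol=1e-8)

    def test_constant_affinity_is_rank_one(self):
        emb = diffusion_embedding(AffinityMatrix(np.ones((20, 20))), k=5)
        np.testing.assert_allclose(emb.eigenvalues, 0.0, atol=1e-10)
        np.testing.assert_allclose(emb.scores, 0.0, atol=1e-8)

    def test_disconnected_affinity_rejected(self):
        a = np.zeros((20, 20))
        a[:10, :10] = 0.8
        a[10:, 10:] = 0.8
        np.fill_diagonal(a, 1.0)
        with pytest.raises(GraphError):
            diffusion_embedding(AffinityMatrix(a), k=3)

    def test_eigenvalues_nonincreasing_and_variance_fractions(self, small_connectome):
        cm, _ = small_connectome
        emb = diffusion_embedding(normalized_angle(threshold_rows(cm, 0.2)), k=10)
        assert (np.diff(emb.eigenvalues) <= 1e-12).all()
        assert emb.variance_explained.sum() <= 1.0 + 1e-12
        assert emb.params["embedding_alpha"] == 0.5
        assert emb.params["diffusion_time"] == 0.0


class TestProcrustes:
    @pytest.fixture()
    def embedding(self, small_connectome):
        cm, _ = small_connectome
        return diffusion_embedding(normalized_angle(threshold_rows(cm, 0.2)), k=5)

    def test_self_alignment_is_identity(self, embedding):
        aligned = procrustes_align(embedding, embedding, n_components=3)
        np.testing.assert_allclose(aligned.scores, embedding.scores[:, :3], atol=1e-10)
        assert aligned.alignment_ref == "reference"

    def test_known_rotation_is_inverted(self, embedding):
        angle = 0.7
        R = np.array([[np.cos(angle), -np.sin(angle), 0],
                      [np.sin(angle), np.cos(angle), 0],
                      [0, 0, 1.0]])
        rotated = GradientEmbedding(scores=embedding.scores[:, :3] @ R,
                                    eigenvalues=embedding.eigenvalues[:3],
                                    variance_explained=embedding.variance_explained[:3])
        aligned = procrustes_align(rotated, embedding, n_components=3)
        np.testing.assert_allclose(aligned.scores, embedding.scores[:, :3], atol=1e-8)

    def test_reflection_corrected(self, embedding):
        flipped = GradientEmbedding(scores=embedding.scores[:, :3] * [1, -1, 1],
                                    eigenvalues=embedding.eigenvalues[:3],
                                    variance_explained=embedding.variance_explained[:3])
        aligned = procrustes_align(flipped, embedding, n_components=3)
        np.testing.assert_allclose(aligned.scores, embedding.scores[:, :3], atol=1e-10)

    def test_pairwise_distances_preserved(self, embedding):
        other = GradientEmbedding(scores=embedding.scores[:, :3][::-1].copy(),
                                  eigenvalues=embedding.eigenvalues[:3],
                                  variance_explained=embedding.variance_explained[:3])
        aligned = procrustes_align(embedding, other, n_components=3)
        before = scipy.spatial.distance.pdist(embedding.scores[:, :3])
        after = scipy.spatial.distance.pdist(aligned.scores)
        np.testing.assert_allclose(before, after, atol=1e-10)

    def test_parcel_mismatch_rejected(self, embedding):
        small = GradientEmbedding(scores=embedding.scores[:10, :3],
                                  eigenvalues=embedding.eigenvalues[:3],
                                  variance_explained=embedding.variance_explained[:3])
        with pytest.raises(InputShapeError):
            procrustes_align(embedding, small)


class TestEccentricity:
    def _emb(self, scores):
        k = scores.shape[1]
        return GradientEmbedding(scores=scores, eigenvalues=np.arange(k, 0, -1.0),
                                 variance_explained=np.full(k, 1.0 / k))

    def test_identical_parcels_have_zero_eccentricity(self):
        emb = self._emb(np.tile([0.3, -0.2, 0.5], (7, 1)))
        np.testing.assert_allclose(eccentricity(emb).values, 0.0, atol=1e-12)

    def test_unit_simplex_example(self):
        emb = self._emb(np.eye(3))
        ecc = eccentricity(emb)
        np.testing.assert_allclose(ecc.values, np.sqrt(6) / 3, atol=1e-12)
        np.testing.assert_allclose(ecc.center_used, 1 / 3)

    def test_rotation_invariance(self, rng):
        scores = rng.normal(size=(15, 3))
        R = scipy.stats.special_ortho_group.rvs(3, random_state=rng)
        a = eccentricity(self._emb(scores)).values
        b = eccentricity(self._emb(scores @ R)).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_origin_center_mode(self):
        emb = self._emb(np.array([[3.0, 4.0, 0.0]] * 4))
        ecc = eccentricity(emb, center="origin")
        np.testing.assert_allclose(ecc.values, 5.0)

    def test_too_few_components_rejected(self):
        emb = GradientEmbedding(scores=np.ones((5, 2)), eigenvalues=[2.0, 1.0],
                                variance_explained=[0.6, 0.4])
        with pytest.raises(InputShapeError):
            eccentricity(emb)


class TestNetworkSummary:
    def test_binary_mask_and_weighted_mean(self):
        w = NetworkWeights(weights={
            "attention": np.array([1.0] * 10 + [0.0] * 5),
            "emotion": np.array([1.0, 3.0] + [0.0] * 13),
        })
        values = np.concatenate([np.full(10, 2.0), np.zeros(5)])
        values[0], values[1] = 0.0, 4.0
        out = network_summary(values, w)
        assert out["emotion"] == pytest.approx(3.0)  # weights (1,3), values (0,4)
        uniform = NetworkWeights(weights={"attention": np.ones(15)})
        assert network_summary(values, uniform)["attention"] == pytest.approx(values.mean())

    def test_length_mismatch_rejected(self):
        w = NetworkWeights(weights={"attention": np.ones(4)})
        with pytest.raises(InputShapeError):
            network_summary(np.ones(5), w)

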