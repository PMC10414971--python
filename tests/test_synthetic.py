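import numpy as np
import pytest

from gradplast.errors import ConfigError, DesignError
from gradplast.io_core import validate_design
from gradplast.synthetic import (
    EffectSpec,
    LatentManifold,
    fibonacci_sphere,
    make_behavior,
    make_cohort,
    make_connectome,
    make_cortex,
    make_smooth_sphere_maps,
)
from gradplast.equivolume import vertex_areas, triangle_areas
from gradplast.longitudinal import change_maps


class TestMakeConnectome:
    def test_two_clusters_give_block_structure(self):
        coords = np.vstack([np.zeros((10, 3)), np.full((10, 3), 5.0)])
        coords += np.random.default_rng(0).normal(0, 0.05, coords.shape)
        cm, _ = make_connectome(LatentManifold(coords=coords, kernel_scale=1.0), seed=0)
        within = np.concatenate([cm.values[:10, :10][np.triu_indices(10, 1)],
                                 cm.values[10:, 10:][np.triu_indices(10, 1)]])
        between = cm.values[:10, 10:].ravel()
        assert within.min() > between.max()

    def test_same_seed_reproducible(self):
        m = LatentManifold.random(30, seed=3, noise_sd=0.05)
        a, _ = make_connectome(m, seed=9)
        b, _ = make_connectome(m, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unit_diagonal_symmetry_and_bounds(self):
        m = LatentManifold.random(40, seed=4, noise_sd=0.2)
        cm, _ = make_connectome(m, seed=4)
        np.testing.assert_allclose(np.diag(cm.values), 1.0)
        assert np.abs(cm.values - cm.values.T).max() == 0
        assert cm.values.min() >= -1 and cm.values.max() <= 1

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigError):
            LatentManifold.random(30, seed=0, noise_sd=-0.1)


class TestMakeCohort:
    def test_zero_variance_zero_effect_gives_zero_change(self):
        spec = EffectSpec.null(8, subject_sd=0.0, residual_sd=0.0)
        design, maps = make_cohort(3, 3, 2, spec, n_parcels=8, seed=5)
        ct = change_maps(maps, design)
        np.testing.assert_array_equal(ct.values, 0.0)

    def test_planted_effect_exact_without_noise(self):
        effect = np.zeros(50)
        effect[:40] = 0.2
        spec = EffectSpec(effect_maps={"Presence": effect, "Affect": np.zeros(50),
                                       "Perspective": np.zeros(50)})
        design, maps = make_cohort(4, 4, 0, spec, n_parcels=50, seed=6)
        ct = change_maps(maps, design)
        presence = ct.values[(ct.frame["tm"] == "Presence").to_numpy()]
        np.testing.assert_allclose(presence, np.tile(effect, (len(presence), 1)))

    def test_mean_change_within_monte_carlo_error(self):
        # planted +0.2 with subject and interval noise: the mean Presence
        # change over 200 training subjects stays within 3 SE of the truth
        effect = np.full(40, 0.2)
        spec = EffectSpec(effect_maps={"Presence": effect, "Affect": np.zeros(40),
                                       "Perspective": np.zeros(40)},
                          subject_sd=0.1, residual_sd=0.1)
        design, maps = make_cohort(100, 100, 0, spec, n_parcels=40, seed=7)
        ct = change_maps(maps, design)
        rows = ct.values[(ct.frame["tm"] == "Presence").to_numpy()]
        se = rows.mean(axis=1).std(ddof=1) / np.sqrt(len(rows))
        assert abs(rows.mean() - 0.2) < 3 * se

    def test_design_satisfies_validator_and_rcc_untrained(self):
        spec = EffectSpec.null(5)
        design, _ = make_cohort(2, 2, 2, spec, n_parcels=5, seed=8, n_tc3=2)
        validate_design(design)  # raises DesignError on any inconsistency
        rcc = design[design.cohort == "RCC"]
        assert (rcc.tm == "None").all()
        tc3 = design[design.cohort == "TC3"]
        assert set(tc3.timepoint) == {"T0", "T1"}
        assert (tc3[tc3.timepoint == "T1"].tm == "Affect").all()

    def test_invalid_cohort_size_rejected(self):
        with pytest.raises(ConfigError):
            make_cohort(-1, 0, 0, EffectSpec.null(4), n_parcels=4, seed=0)


class TestMakeCortex:
    def test_flat_sheet_offsets_along_normal(self):
        sp = make_cortex("sheet", n_vertices=100, thickness=3.0)
        np.testing.assert_allclose(sp.pial_vertices - sp.white_vertices,
                                   np.tile([0, 0, 3.0], (sp.n_vertices, 1)))

    def test_wedge_vertex_area_ratio(self):
        sp = make_cortex("wedge", n_vertices=400, thickness=3.0, area_ratio=2.0)
        ratio = vertex_areas(sp.pial_vertices, sp.faces) / vertex_areas(
            sp.white_vertices, sp.faces)
        assert np.abs(ratio - 2.0).max() < 0.02 * 2.0

    def test_sphere_patch_areas_match_analytic(self):
        sp = make_cortex("sphere_patch", n_vertices=2500, radii=(30.0, 33.0))
        # analytic area of the (theta, phi) patch on a radius-r sphere
        analytic = lambda r: r**2 * (np.cos(0.4) - np.cos(1.1)) * 0.7
        for verts, r in ((sp.white_vertices, 30.0), (sp.pial_vertices, 33.0)):
            measured = triangle_areas(verts, sp.faces).sum()
            assert abs(measured - analytic(r)) < 0.02 * analytic(r)

    def test_sinusoidal_sheet_has_constant_thickness(self):
        sp = make_cortex("sinusoidal_sheet", n_vertices=400, thickness=2.0, amplitude=3.0)
        d = np.linalg.norm(sp.pial_vertices - sp.white_vertices, axis=1)
        np.testing.assert_allclose(d, 2.0, atol=1e-12)


class TestMakeBehavior:
    def test_noise_free_is_exact_linear_map(self, rng):
        X = rng.normal(size=(20, 35))
        w = np.zeros(35)
        w[[1, 5, 9]] = 0.5
        np.testing.assert_array_equal(make_behavior(X, w, noise_sd=0.0, seed=0), X @ w)

    def test_seeded_reproducibility(self, rng):
        X = rng.normal(size=(20, 35))
        w = np.zeros(35)
        a = make_behavior(X, w, noise_sd=1.0, seed=3)
        b = make_behavior(X, w, noise_sd=1.0, seed=3)
        np.testing.assert_array_equal(a, b)
        assert a.std() > 0

    def test_null_weights_give_uncorrelated_target(self, rng):
        X = rng.normal(size=(500, 35))
        y = make_behavior(X, np.zeros(35), noise_sd=1.0, seed=4)
        corr = X.T @ (y - y.mean()) / (np.linalg.norm(X, axis=0) * np.linalg.norm(y - y.mean()))
        assert np.abs(corr).max() < 0.2  # ~4 sigma bound at n=500


class TestSphereHelpers:
    def test_fibonacci_points_on_unit_sphere(self):
        pts = fibonacci_sphere(200)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.abs(pts.mean(axis=0)).max() < 0.05

    def test_smooth_maps_are_standardized_and_autocorrelated(self):
        coords, maps = make_smooth_sphere_maps(150, 3, seed=2, smoothing=0.6)
        np.testing.assert_allclose(maps.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(maps.std(axis=1), 1.0, atol=1e-12)
        # neighbouring parcels correlate strongly after smoothing
        d2 = np.sum((coords[:, None] - coords[None]) ** 2, axis=-1)
        near = d2 < 0.1
        np.fill_diagonal(near, False)
        prods = [maps[k][i] * maps[k][j] for k in range(3)
                 for i, j in zip(*np.nonzero(near))]
        assert np.mean(prods) > 0.5
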