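import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gradplast.equivolume import (
    DepthProfileTable,
    build_laminar_stack,
    compartment_means,
    depth_zscore,
    equivolume_fraction,
    parcel_profiles,
    sample_field,
    vertex_areas,
)
from gradplast.errors import (
    InputShapeError,
    InputValueError,
    MeshError,
    NumericalError,
    ParcellationError,
    SamplingError,
)
from gradplast.io_core import Parcellation
from gradplast.synthetic import (
    AnalyticField,
    make_cortex,
    make_grid_parcellation,
    make_qt1_field,
    sheet_depth_geometry,
)
from gradplast.validation import equivolume_conservation


class TestVertexAreas:
    def test_single_triangle_splits_in_thirds(self):
        # right triangle with legs sqrt(6): area 3, one unit per vertex
        s = np.sqrt(6.0)
        v = np.array([[0, 0, 0], [s, 0, 0], [0, s, 0.0]])
        f = np.array([[0, 1, 2]])
        np.testing.assert_allclose(vertex_areas(v, f), 1.0)

    def test_unit_square_two_triangles(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        f = np.array([[0, 1, 2], [0, 2, 3]])
        areas = vertex_areas(v, f)
        assert areas.sum() == pytest.approx(1.0)
        # diagonal vertices touch both triangles, off-diagonal one each
        np.testing.assert_allclose(areas, [1 / 3, 1 / 6, 1 / 3, 1 / 6])

    def test_scaling_law(self, rng):
        sp = make_cortex("sheet", n_vertices=100)
        a1 = vertex_areas(sp.white_vertices, sp.faces)
        a2 = vertex_areas(sp.white_vertices * 2.5, sp.faces)
        np.testing.assert_allclose(a2, a1 * 2.5**2, rtol=1e-12)

    def test_degenerate_triangle_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(MeshError):
            vertex_areas(v, np.array([[0, 1, 2]]))


class TestSurfaceIO:
    def test_ply_round_trip_preserves_geometry(self, tmp_path):
        from gradplast.equivolume import load_surface_pair, save_surface

        sp = make_cortex("wedge", n_vertices=100, thickness=3.0, area_ratio=2.0)
        save_surface(sp.white_vertices, sp.faces, tmp_path / "white.ply")
        save_surface(sp.pial_vertices, sp.faces, tmp_path / "pial.ply")
        back = load_surface_pair(tmp_path / "white.ply", tmp_path / "pial.ply")
        np.testing.assert_allclose(back.white_vertices, sp.white_vertices, atol=1e-6)
        np.testing.assert_allclose(back.pial_vertices, sp.pial_vertices, atol=1e-6)
        np.testing.assert_array_equal(back.faces, sp.faces)

    def test_topology_mismatch_rejected(self, tmp_path):
        from gradplast.equivolume import load_surface_pair, save_surface

        sp = make_cortex("sheet", n_vertices=64)
        save_surface(sp.white_vertices, sp.faces, tmp_path / "a.ply")
        save_surface(sp.pial_vertices[: len(sp.pial_vertices) // 2],
                     sp.faces[: len(sp.faces) // 4], tmp_path / "b.ply")
        with pytest.raises(MeshError):
            load_surface_pair(tmp_path / "a.ply", tmp_path / "b.ply")


class TestEquivolumeFraction:
    def test_boundary_values(self):
        assert equivolume_fraction(1.3, 2.7, 0.0) == pytest.approx(0.0, abs=1e-15)
        assert equivolume_fraction(1.3, 2.7, 1.0) == pytest.approx(1.0, abs=1e-15)

    def test_equal_areas_limit_is_alpha(self):
        for alpha in (0.1, 0.5, 0.9):
            assert equivolume_fraction(2.0, 2.0, alpha) == pytest.approx(alpha)
            # near-equal areas converge to the same limit
            assert equivolume_fraction(2.0, 2.0 + 1e-14, alpha) == pytest.approx(alpha)

    def test_quadratic_volume_root(self):
        # cumulative volume V(rho) = A_in rho + rho^2 (A_out - A_in)/2 set to
        # alpha V(1): for A_in=1, A_out=2, alpha=.5 the positive root is sqrt(2.5)-1
        assert equivolume_fraction(1.0, 2.0, 0.5) == pytest.approx(np.sqrt(2.5) - 1, abs=1e-12)

    @given(a_in=st.floats(0.1, 10), a_out=st.floats(0.1, 10),
           alpha=st.floats(0, 1), dalpha=st.floats(0.001, 0.5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_alpha_and_bounded(self, a_in, a_out, alpha, dalpha):
        lo = equivolume_fraction(a_in, a_out, alpha)
        hi = equivolume_fraction(a_in, a_out, min(alpha + dalpha, 1.0))
        assert 0.0 <= lo <= hi <= 1.0

    def test_nonpositive_area_rejected(self):
        with pytest.raises(InputValueError):
            equivolume_fraction(0.0, 1.0, 0.5)


class TestLaminarStack:
    def test_flat_sheet_equals_equidistant(self):
        sp = make_cortex("sheet", n_vertices=100, thickness=3.0)
        stack = build_laminar_stack(sp, n_surfaces=12)
        fracs = stack.volume_fractions
        expected = sp.white_vertices[None] + fracs[:, None, None] * (
            sp.pial_vertices - sp.white_vertices)[None]
        assert np.abs(stack.surfaces - expected).max() < 1e-9 * 3.0

    def test_wedge_volume_conservation(self):
        out = equivolume_conservation(n_vertices=400, area_ratio=2.0)
        assert out["volume_rel_spread"] < 1e-3
        assert out["flat_limit_max_dev"] < 1e-9

    def test_single_midvolume_surface_on_flat_sheet(self):
        sp = make_cortex("sheet", n_vertices=64, thickness=2.0)
        stack = build_laminar_stack(sp, n_surfaces=1)
        mid = 0.5 * (sp.white_vertices + sp.pial_vertices)
        np.testing.assert_allclose(stack.surfaces[0], mid, atol=1e-12)

    def test_interior_fractions_and_ordering(self):
        sp = make_cortex("wedge", n_vertices=100, area_ratio=2.0)
        stack = build_laminar_stack(sp, n_surfaces=12)
        # superficial-to-deep: distance fraction from white strictly decreasing
        assert (np.diff(stack.rho, axis=0) < 0).all()
        assert stack.rho.min() > 0 and stack.rho.max() < 1
        np.testing.assert_allclose(stack.volume_fractions,
                                   np.arange(12, 0, -1) / 13.0)


class TestSampleField:
    def test_constant_analytic_field(self):
        sp = make_cortex("sheet", n_vertices=64, thickness=3.0)
        stack = build_laminar_stack(sp, n_surfaces=12)
        field = AnalyticField(lambda pts: np.full(len(pts), 1500.0))
        np.testing.assert_array_equal(sample_field(stack, field), 1500.0)

    def test_linear_depth_profile_recovered_exactly(self):
        thickness = 3.0
        sp = make_cortex("sheet", n_vertices=100, thickness=thickness)
        stack = build_laminar_stack(sp, n_surfaces=12)
        analytic, _ = make_qt1_field(lambda depth, region: 1200.0 + 600.0 * depth,
                                     sheet_depth_geometry(thickness))
        samples = sample_field(stack, analytic)
        # depth fraction of surface d (superficial first) is 1 - rho
        expected = 1200.0 + 600.0 * (1.0 - stack.rho.T)
        np.testing.assert_allclose(samples, expected, atol=1e-6)

    def test_nifti_trilinear_reproduces_linear_field(self):
        thickness = 3.0
        sp = make_cortex("sheet", n_vertices=100, thickness=thickness, extent=10.0)
        stack = build_laminar_stack(sp, n_surfaces=4)
        _, img = make_qt1_field(lambda depth, region: 100.0 + 7.0 * depth,
                                sheet_depth_geometry(thickness),
                                grid_shape=(16, 16, 20),
                                origin=(-2.0, -2.0, -0.5), spacing=(1.0, 1.0, 0.25))
        samples = sample_field(stack, img)
        expected = 100.0 + 7.0 * (1.0 - stack.rho.T)
        np.testing.assert_allclose(samples, expected, atol=1e-9)

    def test_out_of_bounds_fraction_raises(self):
        sp = make_cortex("sheet", n_vertices=100, thickness=3.0, extent=20.0)
        stack = build_laminar_stack(sp, n_surfaces=4)
        _, img = make_qt1_field(lambda depth, region: np.ones_like(depth),
                                sheet_depth_geometry(3.0),
                                grid_shape=(8, 8, 16),
                                origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 0.25))
        with pytest.raises(SamplingError):
            sample_field(stack, img)


class TestParcelProfiles:
    def test_constant_parcels_recovered(self):
        samples = np.vstack([np.full((5, 12), 1400.0), np.full((5, 12), 1600.0)])
        parc = Parcellation(vertex_labels=[1] * 5 + [2] * 5, parcel_ids=("a", "b"))
        table = parcel_profiles(samples, parc)
        np.testing.assert_allclose(table.values[0], 1400.0)
        np.testing.assert_allclose(table.values[1], 1600.0)
        assert table.low_confidence.all()  # fewer than 10 vertices each

    def test_matches_naive_loop_oracle(self, rng):
        samples = rng.normal(size=(200, 12))
        labels = rng.integers(1, 6, size=200)
        parc = Parcellation(vertex_labels=labels, parcel_ids=tuple("abcde"))
        table = parcel_profiles(samples, parc)
        for p in range(5):
            oracle = samples[labels == p + 1].mean(axis=0)
            np.testing.assert_allclose(table.values[p], oracle, atol=1e-12)

    def test_all_unassigned_rejected(self):
        parc = make_grid_parcellation(10, 2)
        parc.vertex_labels[:] = 0
        with pytest.raises(ParcellationError):
            parcel_profiles(np.ones((10, 12)), parc)


class TestDepthZscoreAndCompartments:
    def test_two_point_population_standardization(self):
        t = DepthProfileTable(values=np.array([[1.0] * 12, [3.0] * 12]),
                              parcel_ids=("a", "b"))
        z = depth_zscore(t)
        np.testing.assert_allclose(z.values[0], -1.0)
        np.testing.assert_allclose(z.values[1], 1.0)

    def test_matches_column_standardization_oracle(self, rng):
        values = rng.normal(size=(5, 12)) * 100 + 1400
        z = depth_zscore(DepthProfileTable(values=values, parcel_ids=tuple("abcde")))
        oracle = (values - values.mean(0)) / values.std(0)
        np.testing.assert_allclose(z.values, oracle, atol=1e-12)
        np.testing.assert_allclose(z.values.mean(0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(0), 1.0, atol=1e-12)

    def test_zero_variance_column_rejected(self):
        t = DepthProfileTable(values=np.ones((3, 12)), parcel_ids=("a", "b", "c"))
        with pytest.raises(NumericalError):
            depth_zscore(t)

    def test_compartment_means_on_ramp(self):
        t = DepthProfileTable(values=np.arange(1.0, 13.0)[None, :], parcel_ids=("a",))
        out = compartment_means(t)
        assert out["superficial"][0] == pytest.approx(2.5)
        assert out["middle"][0] == pytest.approx(6.5)
        assert out["deep"][0] == pytest.approx(10.5)
        const = DepthProfileTable(values=np.full((1, 12), 7.0), parcel_ids=("a",))
        assert all(v[0] == pytest.approx(7.0) for v in compartment_means(const).values())

    def test_wrong_depth_count_rejected(self):
        t = DepthProfileTable(values=np.ones((2, 11)), parcel_ids=("a", "b"))
        with pytest.raises(InputShapeError):
            compartment_means(t)
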