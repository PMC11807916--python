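import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree

from atriarecon.grid import GridSpec, OccupancyVolume
from atriarecon.shapemodel import (
    _N_PARAMS,
    PV_NAMES,
    AtriumShape,
    LandmarkSet,
    ShapeModelSpec,
    ShapeParams,
    build_atrium,
    default_shape_model,
    generate_dataset,
    passes_plausibility,
    plausibility_score,
    points_in_mesh,
    sample_shape_params,
    voxelize_shape,
)
from tests.conftest import COARSE_GRID


class TestSampling:
    def test_zero_covariance_returns_mean(self, shape_model):
        degenerate = ShapeModelSpec(
            mean=shape_model.mean, covariance=np.zeros_like(shape_model.covariance)
        )
        p = sample_shape_params(degenerate, seed=123)
        np.testing.assert_allclose(p.to_vector(), shape_model.mean)

    def test_deterministic_per_seed(self, shape_model):
        a = sample_shape_params(shape_model, seed=7)
        b = sample_shape_params(shape_model, seed=7)
        np.testing.assert_array_equal(a.to_vector(), b.to_vector())

    def test_sample_mean_converges_to_model_mean(self, shape_model):
        # law of large numbers on one scalar parameter (body x semi-axis)
        rng = np.random.default_rng(99)
        draws = np.array([shape_model.sample_vector(rng)[0] for _ in range(1000)])
        sigma = np.sqrt(shape_model.covariance[0, 0])
        assert abs(draws.mean() - shape_model.mean[0]) < 3 * sigma / np.sqrt(1000)

    def test_non_psd_covariance_rejected(self):
        cov = -np.eye(_N_PARAMS)
        with pytest.raises(ValueError):
            ShapeModelSpec(mean=np.zeros(_N_PARAMS), covariance=cov)


class TestPlausibility:
    def test_mean_attains_maximal_score(self, shape_model):
        mean_score = plausibility_score(
            ShapeParams.from_vector(shape_model.mean), shape_model
        )
        assert mean_score == 0.0
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = ShapeParams.from_vector(shape_model.sample_vector(rng))
            assert plausibility_score(p, shape_model) <= mean_score

    def test_five_units_out_fails_default_threshold(self, shape_model):
        # walk 5 Mahalanobis units along the leading covariance mode
        w, v = np.linalg.eigh(shape_model.covariance)
        vec = shape_model.mean + 5.0 * np.sqrt(w[-1]) * v[:, -1]
        params = ShapeParams.from_vector(vec)
        assert shape_model.mahalanobis(vec) == pytest.approx(5.0)
        assert not passes_plausibility(params, shape_model)
        assert plausibility_score(params, shape_model) < -0.5 * 3.0**2

    def test_score_invariant_to_pv_block_reordering(self):
        # identical PV parameter blocks + block-symmetric (diagonal) covariance
        mean = default_shape_model().mean.copy()
        blk = mean[4:10].copy()
        for i in range(4):
            mean[4 + 6 * i : 10 + 6 * i] = blk
        cov = np.diag(np.full(_N_PARAMS, 0.5))
        model = ShapeModelSpec(mean=mean, covariance=cov)
        rng = np.random.default_rng(3)
        vec = model.sample_vector(rng)
        swapped = vec.copy()
        swapped[4:10], swapped[10:16] = vec[10:16].copy(), vec[4:10].copy()
        s1 = plausibility_score(ShapeParams.from_vector(vec), model)
        s2 = plausibility_score(ShapeParams.from_vector(swapped), model)
        assert s1 == pytest.approx(s2, rel=1e-12)


class TestBuildAtrium:
    def test_mean_shape_fits_default_grid_with_margin(self, shape_model):
        shape = build_atrium(ShapeParams.from_vector(shape_model.mean))
        half_extent = GridSpec().extent_mm / 2  # grid centred on origin
        bounds = shape.mesh.bounds
        assert np.all(bounds[0] > -half_extent + 5.0)
        assert np.all(bounds[1] < half_extent - 5.0)

    def test_surface_is_closed_genus_zero(self, small_dataset):
        for shape, _ in small_dataset[:5]:
            assert shape.mesh.is_watertight
            assert shape.mesh.euler_number == 2

    def test_landmarks_lie_on_the_surface(self, small_dataset):
        spacing = COARSE_GRID.spacing
        for shape, _ in small_dataset:
            tree = cKDTree(shape.mesh.vertices)
            for name, p in shape.landmarks.points.items():
                d, _ = tree.query(p)
                assert d <= 2 * spacing, f"{name} is {d:.1f} mm off the surface"

    def test_pv_directions_too_close_rejected(self, shape_model):
        params = ShapeParams.from_vector(shape_model.mean)
        params.pvs["PVLI"].direction = params.pvs["PVLS"].direction.copy()
        with pytest.raises(ValueError, match="separated"):
            build_atrium(params)


class TestVoxelize:
    def _sphere_shape(self, radius=20.0):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=radius)
        on_surf = mesh.vertices[0]
        lms = LandmarkSet({
            "septum": on_surf,
            **{f"ostium_{p}": mesh.vertices[i + 1] for i, p in enumerate(PV_NAMES)},
        })
        return AtriumShape(mesh=mesh, landmarks=lms, sdf=None)

    def test_ball_volume_within_five_percent(self):
        grid = GridSpec()
        vol = voxelize_shape(self._sphere_shape(20.0), grid)
        analytic = 4.0 / 3.0 * np.pi * 20.0**3 / grid.spacing**3
        assert abs(vol.count() - analytic) / analytic < 0.05

    def test_region_far_from_mesh_stays_empty(self):
        grid = GridSpec()
        vol = voxelize_shape(self._sphere_shape(15.0), grid)
        assert vol.values[:5].sum() == 0 and vol.values[-5:].sum() == 0

    def test_boundary_shell_is_single_connected_component(self, one_shape):
        from scipy import ndimage

        _, vol = one_shape
        shell = vol.boundary()
        _, n = ndimage.label(shell, structure=ndimage.generate_binary_structure(3, 3))
        assert n == 1

    def test_mesh_exceeding_grid_names_axis(self):
        small = GridSpec(dims=(8, 8, 8), spacing=2.0)
        with pytest.raises(ValueError, match="axis [xyz]"):
            voxelize_shape(self._sphere_shape(20.0), small)

    def test_winding_number_matches_analytic_ball(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-15, 15, size=(500, 3))
        expect = np.linalg.norm(pts, axis=1) <= 10.0
        got = points_in_mesh(mesh, pts)
        # disagreement only possible within a facet's sagitta of the surface
        near = np.abs(np.linalg.norm(pts, axis=1) - 10.0) < 0.5
        assert np.array_equal(got[~near], expect[~near])


class TestGenerateDataset:
    def test_deterministic_and_disjoint(self, shape_model):
        g = COARSE_GRID
        t1, s1 = generate_dataset(2, 1, shape_model, g, seed=5, mesh_resolution=2.5)
        t2, s2 = generate_dataset(2, 1, shape_model, g, seed=5, mesh_resolution=2.5)
        assert len(t1) == 2 and len(s1) == 1
        for (a, va), (b, vb) in zip(t1 + s1, t2 + s2):
            np.testing.assert_array_equal(va.values, vb.values)
            np.testing.assert_array_equal(a.mesh.vertices, b.mesh.vertices)

    def test_zero_test_split_allowed(self, shape_model):
        train, test = generate_dataset(1, 0, shape_model, COARSE_GRID, seed=2,
                                       mesh_resolution=2.5)
        assert len(train) == 1 and test == []

    def test_all_samples_pass_plausibility_recheck(self, small_dataset, shape_model):
        for shape, _ in small_dataset:
            assert passes_plausibility(shape.params, shape_model)

    def test_interiors_are_single_components(self, small_dataset):
        for _, vol in small_dataset:
            assert vol.count() > 0
            assert vol.n_components() == 1
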