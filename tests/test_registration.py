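import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from atriarecon.grid import GridSpec, OccupancyVolume, binarize
from atriarecon.paths import PathPointCloud
from atriarecon.registration import (
    MeanShape,
    RigidTransform,
    apply_transform,
    compute_mean_shape,
    preprocess_clinical,
    rigid_register,
)
from atriarecon.shapemodel import PV_NAMES, LandmarkSet


def random_rigid(rng) -> RigidTransform:
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-30, 30, 3)
    return RigidTransform(R, t)


def ostia_square(side=30.0):
    return np.array([
        [side, 0.0, side / 2],
        [side, 0.0, -side / 2],
        [-side, 0.0, -side / 2],
        [-side, 0.0, side / 2],
    ])


class TestRigidTransform:
    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_inverse_round_trip_and_isometry(self):
        rng = np.random.default_rng(0)
        T = random_rigid(rng)
        pts = rng.uniform(-50, 50, (20, 3))
        back = T.inverse().apply(T.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        moved = T.apply(pts)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)


class TestRigidRegister:
    def test_identity_for_identical_sets(self):
        pts = ostia_square()
        T = rigid_register(pts, pts)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-12)

    def test_recovers_synthesized_motion(self):
        rng = np.random.default_rng(1)
        src = ostia_square()
        for _ in range(20):
            T0 = random_rigid(rng)
            T = rigid_register(src, T0.apply(src))
            np.testing.assert_allclose(T.rotation, T0.rotation, atol=1e-9)
            np.testing.assert_allclose(T.translation, T0.translation, atol=1e-9)

    def test_quarter_turn_has_zero_residual(self):
        src = ostia_square()
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        T = rigid_register(src, src @ Rz.T)
        resid = np.linalg.norm(T.apply(src) - src @ Rz.T)
        assert resid < 1e-12

    def test_agrees_with_scipy_align_vectors(self):
        # independent solver for the same least-squares rotation
        rng = np.random.default_rng(2)
        src = ostia_square() + rng.normal(0, 2.0, (4, 3))
        dst = random_rigid(rng).apply(src) + rng.normal(0, 0.5, (4, 3))
        T = rigid_register(src, dst)
        sc, dc = src - src.mean(0), dst - dst.mean(0)
        R_ref, _ = Rotation.align_vectors(dc, sc)
        np.testing.assert_allclose(T.rotation, R_ref.as_matrix(), atol=1e-9)

    def test_collinear_points_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            rigid_register(src, src)

    def test_noise_robustness_of_rotation(self):
        # 1 mm landmark noise on 4-point sets: rotation error < 5 degrees
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(100):
            T0 = random_rigid(rng)
            src = ostia_square()
            noisy = T0.apply(src) + rng.normal(0, 1.0, (4, 3))
            T = rigid_register(src, noisy)
            dR = Rotation.from_matrix(T.rotation.T @ T0.rotation)
            errs.append(np.degrees(dR.magnitude()))
        assert np.max(errs) < 5.0


class TestMeanShape:
    def _vol(self, grid, fill):
        vals = np.zeros(grid.dims, np.uint8)
        vals[fill] = 1
        return OccupancyVolume(grid, vals)

    def _lms(self, offset=0.0):
        return LandmarkSet({
            "septum": np.array([-20.0, 0, 0]) + offset,
            **{f"ostium_{p}": q + offset
               for p, q in zip(PV_NAMES, ostia_square(20.0))},
        })

    def test_single_volume_mean_is_itself(self):
        g = GridSpec(dims=(6, 6, 6))
        v = self._vol(g, (slice(2, 4),) * 3)
        ms = compute_mean_shape([v], [self._lms()])
        np.testing.assert_array_equal(ms.mean_field, v.values)

    def test_two_disjoint_volumes_average_to_half(self):
        g = GridSpec(dims=(6, 6, 6))
        a = self._vol(g, (slice(0, 2), slice(None), slice(None)))
        b = self._vol(g, (slice(4, 6), slice(None), slice(None)))
        ms = compute_mean_shape([a, b], [self._lms(), self._lms(2.0)])
        assert set(np.unique(ms.mean_field)) == {0.0, 0.5}
        # the >= 0.5 binarization rule keeps both halves
        assert ms.binarized().count() == a.count() + b.count()

    def test_landmarks_are_arithmetic_means(self):
        g = GridSpec(dims=(6, 6, 6))
        v = self._vol(g, (slice(2, 4),) * 3)
        ms = compute_mean_shape([v, v], [self._lms(0.0), self._lms(4.0)])
        np.testing.assert_allclose(ms.landmarks["septum"], [-18.0, 2.0, 2.0])

    def test_grid_mismatch_rejected(self):
        a = self._vol(GridSpec(dims=(6, 6, 6)), (slice(0, 2),))
        b = self._vol(GridSpec(dims=(7, 7, 7)), (slice(0, 2),))
        with pytest.raises(ValueError):
            compute_mean_shape([a, b], [self._lms(), self._lms()])

    def test_benchmark_mean_volume_is_valid_single_component(self, small_dataset):
        ms = compute_mean_shape([v for _, v in small_dataset],
                                [s.landmarks for s, _ in small_dataset])
        assert 0.0 <= ms.mean_field.min() and ms.mean_field.max() <= 1.0
        binar = ms.binarized()
        assert binar.count() > 0 and binar.n_components() == 1


class TestPreprocessClinical:
    def _mean_shape(self):
        g = GridSpec(dims=(24, 24, 24), spacing=5.0)
        c = g.voxel_centers()
        inside = (np.linalg.norm(c, axis=-1) <= 40).astype(np.uint8)
        lms = LandmarkSet({
            "septum": np.array([-40.0, 0, 0]),
            **{f"ostium_{p}": q for p, q in zip(PV_NAMES, ostia_square(28.0))},
        })
        return MeanShape(grid=g, mean_field=inside.astype(float), landmarks=lms)

    def _cloud(self, rng, n=80):
        pts = rng.uniform(-30, 30, (n, 3))
        return PathPointCloud(pts, np.array(["unknown"] * n, dtype=object))

    def test_identity_when_already_aligned(self):
        ms = self._mean_shape()
        rng = np.random.default_rng(0)
        cloud = self._cloud(rng)
        tags = {p: ms.ostia()[p][None, :] for p in PV_NAMES}
        vol, T = preprocess_clinical(cloud, tags, ms)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-9)

    def test_invariant_under_rigid_motion_of_the_cloud(self):
        ms = self._mean_shape()
        rng = np.random.default_rng(1)
        cloud = self._cloud(rng)
        tags = {p: ms.ostia()[p][None, :] for p in PV_NAMES}
        vol0, _ = preprocess_clinical(cloud, tags, ms)
        R = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        T0 = RigidTransform(R, np.array([5.0, -3.0, 8.0]))
        moved = apply_transform(cloud, T0)
        moved_tags = {p: T0.apply(tags[p]) for p in PV_NAMES}
        vol1, _ = preprocess_clinical(moved, moved_tags, ms)
        np.testing.assert_array_equal(vol0.values, vol1.values)

    def test_missing_pv_tag_names_the_vein(self):
        ms = self._mean_shape()
        cloud = self._cloud(np.random.default_rng(2))
        tags = {p: ms.ostia()[p][None, :] for p in PV_NAMES if p != "PVRI"}
        with pytest.raises(ValueError, match="PVRI"):
            preprocess_clinical(cloud, tags, ms)

    def test_single_tagged_point_is_its_own_centroid(self):
        ms = self._mean_shape()
        rng = np.random.default_rng(3)
        cloud = self._cloud(rng)
        single = {p: ms.ostia()[p][None, :] for p in PV_NAMES}
        multi = {p: np.repeat(ms.ostia()[p][None, :], 3, axis=0) for p in PV_NAMES}
        v1, _ = preprocess_clinical(cloud, single, ms)
        v2, _ = preprocess_clinical(cloud, multi, ms)
        np.testing.assert_array_equal(v1.values, v2.values)
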