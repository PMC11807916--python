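"""Mean-shape baseline and rigid-landmark preprocessing.

The mean shape — a voxel-wise average of the training occupancy volumes,
binarized at 0.5 — is both the no-learning baseline reconstruction and
the reference coordinate frame: clinical-style point clouds are rigidly
registered so their four tagged PV-ostium centroids match the mean
shape's ostia in the least-squares sense, then voxelized into the
network input grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, OccupancyVolume, binarize
from .paths import PathPointCloud, path_to_volume
from .shapemodel import PV_NAMES, LandmarkSet


@dataclass
class RigidTransform:
    """Proper rigid motion p -> R p + t (no scale, no reflection)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1, no reflection)")
        self.rotation, self.translation = R, t

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class MeanShape:
    """Voxel-wise average of training volumes with mean landmarks."""

    grid: GridSpec
    mean_field: np.ndarray = field(repr=False)  # in [0, 1]
    landmarks: LandmarkSet = None

    def __post_init__(self) -> None:
        if self.mean_field.min() < 0 or self.mean_field.max() > 1:
            raise ValueError("mean field must lie in [0, 1]")

    def binarized(self, threshold: float = 0.5) -> OccupancyVolume:
        return OccupancyVolume(
            grid=self.grid,
            values=(self.mean_field >= threshold).astype(np.uint8),
        )

    def ostia(self) -> dict[str, np.ndarray]:
        return self.landmarks.ostia()


def compute_mean_shape(
    volumes: list[OccupancyVolume], landmark_sets: list[LandmarkSet]
) -> MeanShape:
    """Voxel-wise arithmetic mean + arithmetic mean of landmark positions."""
    if not volumes:
        raise ValueError("need at least one volume")
    grid = volumes[0].grid
    for v in volumes[1:]:
        if v.grid.dims != grid.dims or v.grid.spacing != grid.spacing:
            raise ValueError("all volumes must share one grid")
    mean_field = np.mean([v.values for v in volumes], axis=0)
    names = set(landmark_sets[0].points)
    for ls in landmark_sets[1:]:
        names &= set(ls.points)
    mean_lms = {n: np.mean([ls[n] for ls in landmark_sets], axis=0) for n in names}
    return MeanShape(grid=grid, mean_field=mean_field, landmarks=LandmarkSet(mean_lms))


def rigid_register(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid alignment of matched point sets (Kabsch/SVD).

    Minimizes sum ||R s_i + t - t_i||^2 over proper rotations R and
    translations t; the SVD sign correction prevents reflections.
    Requires >= 3 non-collinear correspondences.
    """
    s = np.atleast_2d(np.asarray(source, dtype=float))
    t = np.atleast_2d(np.asarray(target, dtype=float))
    if s.shape != t.shape or s.shape[0] < 3:
        raise ValueError("need >= 3 matched point pairs of equal count")
    sc = s - s.mean(axis=0)
    tc = t - t.mean(axis=0)
    H = sc.T @ tc
    U, sig, Vt = np.linalg.svd(H)
    # collinear sets leave the rotation about the line unconstrained
    if sig[1] < 1e-9 * max(sig[0], 1.0):
        raise ValueError("points are collinear/degenerate; rotation is ambiguous")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    trans = t.mean(axis=0) - R @ s.mean(axis=0)
    return RigidTransform(R, trans)


def apply_transform(cloud: PathPointCloud, T: RigidTransform) -> PathPointCloud:
    """Map every point p -> R p + t; labels are preserved."""
    return PathPointCloud(T.apply(cloud.points), cloud.labels.copy(),
                          cloud.source_shape_id)


def preprocess_clinical(
    cloud: PathPointCloud,
    tagged_pv_points: dict[str, np.ndarray],
    mean_shape: MeanShape,
    grid: GridSpec | None = None,
) -> tuple[OccupancyVolume, RigidTransform]:
    """Tagged cloud -> registered occupancy volume on the network grid.

    Per-PV centroids of the physician-tagged points are rigidly aligned
    to the mean shape's ostia; the transform is applied to the whole
    cloud, which is then binned into voxels.  Returns the input volume
    and the recovered transform.
    """
    grid = grid if grid is not None else mean_shape.grid
    missing = [p for p in PV_NAMES if p not in tagged_pv_points
               or len(np.atleast_2d(tagged_pv_points[p])) == 0]
    if missing:
        raise ValueError(f"missing tagged points for PV(s): {missing}")
    centroids = np.array(
        [np.atleast_2d(tagged_pv_points[p]).mean(axis=0) for p in PV_NAMES]
    )
    targets = np.array([mean_shape.ostia()[p] for p in PV_NAMES])
    T = rigid_register(centroids, targets)
    moved = apply_transform(cloud, T)
    return path_to_volume(moved, grid), T
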