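"""Synthetic left-atrium shape generation.

Real statistical shape models of the left atrium are learned from CT
segmentations and are not publicly available, so this module provides a
documented parametric stand-in: a superellipsoid chamber body (optionally
bent), four capsule-shaped pulmonary-vein (PV) tubes anchored on the body
surface, and a hemispherical appendage bump, all blended with a soft-min
over signed-distance fields.  Shape parameters are drawn from a
multivariate normal whose default covariance is low-rank (8 latent
modes), mimicking a PCA-truncated statistical shape model; samples are
kept only if their Mahalanobis distance from the mean stays below a
plausibility threshold.

The generator emits watertight triangular meshes with named anatomical
landmarks (septum, four PV ostia, appendage) plus binary occupancy
volumes on a configurable voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.optimize import brentq
from skimage import measure

from .grid import GridSpec, OccupancyVolume

PV_NAMES: tuple[str, ...] = ("PVLS", "PVLI", "PVRI", "PVRS")
LANDMARK_NAMES: tuple[str, ...] = ("septum",) + tuple(f"ostium_{p}" for p in PV_NAMES)

#: soft-min blend width between primitives, mm
BLEND_WIDTH_MM = 4.0
#: superellipsoid exponent of the chamber body (2 = ellipsoid; >2 boxier)
BODY_EXPONENT = 2.2
#: minimum pairwise angular separation of PV directions, degrees
MIN_PV_SEPARATION_DEG = 20.0

_N_PARAMS = 35  # 3 axes + bend + 4*(3 dir + offset + radius + length) + 3+1 app + 3 sep


class ShapeRejectionError(RuntimeError):
    """Raised when sampled parameters produce a degenerate surface."""


# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------

_SL_BODY = slice(0, 3)
_SL_BEND = 3
_SL_PV = {name: slice(4 + 6 * i, 10 + 6 * i) for i, name in enumerate(PV_NAMES)}
_SL_APP_DIR = slice(28, 31)
_SL_APP_SIZE = 31
_SL_SEP_DIR = slice(32, 35)


@dataclass
class PVParams:
    """One pulmonary-vein tube: outward direction, anchoring and size."""

    direction: np.ndarray  # outward axis (normalized on use)
    offset: float  # mm the tube root is pulled inside the body for blending
    radius: float  # mm
    length: float  # mm protrusion beyond the body surface


@dataclass
class ShapeParams:
    """Full parameter set of one synthetic atrium."""

    body_axes: np.ndarray  # superellipsoid semi-axes, mm
    bend: float  # quadratic bend amplitude, mm
    pvs: dict[str, PVParams]
    appendage_direction: np.ndarray
    appendage_size: float  # mm (bump radius)
    septum_direction: np.ndarray

    def to_vector(self) -> np.ndarray:
        v = np.empty(_N_PARAMS)
        v[_SL_BODY] = self.body_axes
        v[_SL_BEND] = self.bend
        for name in PV_NAMES:
            pv = self.pvs[name]
            v[_SL_PV[name]] = [*pv.direction, pv.offset, pv.radius, pv.length]
        v[_SL_APP_DIR] = self.appendage_direction
        v[_SL_APP_SIZE] = self.appendage_size
        v[_SL_SEP_DIR] = self.septum_direction
        return v

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ShapeParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (_N_PARAMS,):
            raise ValueError(f"parameter vector must have shape ({_N_PARAMS},)")
        pvs = {}
        for name in PV_NAMES:
            blk = v[_SL_PV[name]]
            pvs[name] = PVParams(
                direction=blk[:3].copy(),
                offset=float(blk[3]),
                radius=float(blk[4]),
                length=float(blk[5]),
            )
        return cls(
            body_axes=v[_SL_BODY].copy(),
            bend=float(v[_SL_BEND]),
            pvs=pvs,
            appendage_direction=v[_SL_APP_DIR].copy(),
            appendage_size=float(v[_SL_APP_SIZE]),
            septum_direction=v[_SL_SEP_DIR].copy(),
        )

    def validate(self) -> None:
        v = self.to_vector()
        if not np.all(np.isfinite(v)):
            raise ValueError("shape parameters must be finite")
        if np.any(self.body_axes <= 0):
            raise ValueError("body semi-axes must be positive")
        for name in PV_NAMES:
            pv = self.pvs[name]
            if pv.radius <= 0 or pv.length <= 0:
                raise ValueError(f"{name}: tube radius and length must be positive")
        if self.appendage_size <= 0:
            raise ValueError("appendage size must be positive")
        dirs = [_unit(self.pvs[n].direction) for n in PV_NAMES]
        cos_lim = np.cos(np.deg2rad(MIN_PV_SEPARATION_DEG))
        for i in range(4):
            for j in range(i + 1, 4):
                if float(dirs[i] @ dirs[j]) > cos_lim:
                    raise ValueError(
                        f"PV directions {PV_NAMES[i]} and {PV_NAMES[j]} are "
                        f"separated by less than {MIN_PV_SEPARATION_DEG} degrees"
                    )


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


# ---------------------------------------------------------------------------
# statistical model
# ---------------------------------------------------------------------------


@dataclass
class ShapeModelSpec:
    """MVN over the shape-parameter vector plus a plausibility threshold.

    ``threshold`` is a Mahalanobis distance: samples farther than this from
    the mean (measured in the metric of ``covariance``, restricted to its
    support for rank-deficient covariances) are considered implausible.
    """

    mean: np.ndarray
    covariance: np.ndarray
    threshold: float = 3.0

    # eigendecomposition cache
    _eigvals: np.ndarray = field(default=None, repr=False, compare=False)
    _eigvecs: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        n = self.mean.shape[0]
        if self.covariance.shape != (n, n):
            raise ValueError("covariance shape must match mean length")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        w, v = np.linalg.eigh(self.covariance)
        if w.min() < -1e-8 * max(1.0, abs(w.max())):
            raise ValueError("covariance must be positive semi-definite")
        self._eigvals = np.clip(w, 0.0, None)
        self._eigvecs = v

    @property
    def n_params(self) -> int:
        return self.mean.shape[0]

    def _support(self) -> tuple[np.ndarray, np.ndarray]:
        tol = 1e-10 * max(1.0, float(self._eigvals.max(initial=0.0)))
        keep = self._eigvals > tol
        return self._eigvals[keep], self._eigvecs[:, keep]

    def sample_vector(self, rng: np.random.Generator) -> np.ndarray:
        w, v = self._support()
        z = rng.standard_normal(w.shape[0])
        return self.mean + v @ (np.sqrt(w) * z)

    def mahalanobis(self, vector: np.ndarray) -> float:
        """Distance in the covariance metric; inf off the support."""
        diff = np.asarray(vector, dtype=float) - self.mean
        w, v = self._support()
        coeff = v.T @ diff
        resid = diff - v @ coeff
        scale = max(1.0, float(np.linalg.norm(diff)))
        if np.linalg.norm(resid) > 1e-6 * scale:
            return float("inf")
        return float(np.sqrt(np.sum(coeff**2 / w)))


def sample_shape_params(model: ShapeModelSpec, seed: int) -> ShapeParams:
    """Draw one parameter set from the model's MVN (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    return ShapeParams.from_vector(model.sample_vector(rng))


def plausibility_score(params: ShapeParams, model: ShapeModelSpec) -> float:
    """MVN log-density of ``params`` up to an additive constant.

    Returns ``-d^2/2`` where ``d`` is the Mahalanobis distance; the mean
    therefore attains the maximal score of 0.  Parameters off the support
    of a rank-deficient covariance score ``-inf``.
    """
    d = model.mahalanobis(params.to_vector())
    return -0.5 * d * d


def passes_plausibility(params: ShapeParams, model: ShapeModelSpec) -> bool:
    return model.mahalanobis(params.to_vector()) <= model.threshold


def _default_mean() -> np.ndarray:
    p = ShapeParams(
        body_axes=np.array([32.0, 27.0, 23.0]),
        bend=3.0,
        pvs={
            # +x left, -y posterior, +z superior; PVs exit the posterior wall
            "PVLS": PVParams(np.array([0.75, -0.45, 0.50]), 4.0, 6.5, 18.0),
            "PVLI": PVParams(np.array([0.80, -0.42, -0.42]), 4.0, 6.0, 16.0),
            "PVRI": PVParams(np.array([-0.80, -0.42, -0.42]), 4.0, 6.0, 16.0),
            "PVRS": PVParams(np.array([-0.75, -0.45, 0.50]), 4.0, 6.5, 18.0),
        },
        appendage_direction=np.array([0.45, 0.80, 0.35]),
        appendage_size=10.0,
        septum_direction=np.array([-0.90, -0.25, 0.0]),
    )
    return p.to_vector()


def _default_scales() -> np.ndarray:
    s = np.empty(_N_PARAMS)
    s[_SL_BODY] = 2.0
    s[_SL_BEND] = 1.0
    for name in PV_NAMES:
        s[_SL_PV[name]] = [0.06, 0.06, 0.06, 0.5, 0.6, 2.5]
    s[_SL_APP_DIR] = 0.06
    s[_SL_APP_SIZE] = 1.2
    s[_SL_SEP_DIR] = 0.05
    return s


def default_shape_model(n_modes: int = 8, threshold: float = 3.0) -> ShapeModelSpec:
    """Default shape model: 8 latent modes spread over all 35 parameters.

    The mode-mixing matrix is frozen (seeded) so the model is a fixed,
    documented object; per-parameter standard deviations are anatomically
    plausible spreads around a four-PV adult left atrium.
    """
    mix_rng = np.random.default_rng(20240916)
    mix = mix_rng.standard_normal((_N_PARAMS, n_modes))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    modes = _default_scales()[:, None] * mix
    cov = modes @ modes.T
    return ShapeModelSpec(mean=_default_mean(), covariance=cov, threshold=threshold)


# ---------------------------------------------------------------------------
# geometry: signed-distance construction
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """Named anatomical landmark points in mm."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise ValueError(f"missing mandatory landmarks: {missing}")
        for name, p in self.points.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name} must be a finite 3-vector")
            self.points[name] = p

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def ostia(self) -> dict[str, np.ndarray]:
        return {p: self.points[f"ostium_{p}"] for p in PV_NAMES}


@dataclass
class AtriumShape:
    """Watertight surface mesh + landmarks of one synthetic atrium.

    ``sdf`` is the analytic signed-distance-like field the mesh was
    extracted from (negative inside); shapes loaded from disk may lack it,
    in which case interior queries fall back to a generalized winding
    number on the mesh.
    """

    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    sdf: object = None  # callable (n,3) mm -> (n,) or None
    params: ShapeParams | None = None

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Inside-or-on test for mm points (True = interior/boundary)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.sdf is not None:
            return np.asarray(self.sdf(pts)) <= 0.0
        return points_in_mesh(self.mesh, pts)


def _softmin(fields: list[np.ndarray], k: float = BLEND_WIDTH_MM) -> np.ndarray:
    stack = np.stack(fields, axis=0)
    m = stack.min(axis=0)
    return m - k * np.log(np.sum(np.exp(-(stack - m) / k), axis=0))


def _capsule_sdf(p: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(p - closest, axis=1) - r


def _body_radial(p: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Superellipsoid radial function (1 on the surface, <1 inside)."""
    q = np.abs(p) / axes
    return np.power(np.sum(np.power(q, BODY_EXPONENT), axis=1), 1.0 / BODY_EXPONENT)


def make_sdf(params: ShapeParams):
    """Assemble the blended signed-distance field of the full shape.

    The returned callable maps (n, 3) mm points to approximate signed
    distances (exact zero level set; distances near the surface accurate
    to within the blend width).  A quadratic bend along z warps the whole
    shape: world points are mapped back to the canonical frame before the
    primitives are evaluated.
    """
    axes = np.asarray(params.body_axes, dtype=float)
    bend, cz = float(params.bend), float(axes[2])
    body_scale = float(axes.min())

    def surface_anchor(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = _unit(direction)
        t_s = 1.0 / float(_body_radial(d[None, :], axes)[0])
        return d, d * t_s

    tubes = []
    for name in PV_NAMES:
        pv = params.pvs[name]
        d, anchor = surface_anchor(pv.direction)
        a = anchor - d * pv.offset
        b = anchor + d * pv.length
        tubes.append((a, b, pv.radius))

    app_d, app_anchor = surface_anchor(params.appendage_direction)
    app_r = float(params.appendage_size)

    def warp(p: np.ndarray) -> np.ndarray:
        q = np.array(p, dtype=float, copy=True)
        q[:, 0] += bend * (q[:, 2] / cz) ** 2
        return q

    def sdf(points: np.ndarray) -> np.ndarray:
        p = warp(np.atleast_2d(np.asarray(points, dtype=float)))
        fields = [(_body_radial(p, axes) - 1.0) * body_scale]
        for a, b, r in tubes:
            fields.append(_capsule_sdf(p, a, b, r))
        fields.append(np.linalg.norm(p - app_anchor, axis=1) - app_r)
        return _softmin(fields)

    sdf.tubes = tubes  # canonical-frame tube segments, used for landmarks
    sdf.warp = warp
    return sdf


def _unwarp_point(p_canon: np.ndarray, params: ShapeParams) -> np.ndarray:
    """Map a canonical-frame point to world coordinates (inverse bend)."""
    q = np.array(p_canon, dtype=float, copy=True)
    q[0] -= params.bend * (q[2] / params.body_axes[2]) ** 2
    return q


def _surface_point_along(sdf, start: np.ndarray, direction: np.ndarray,
                         t_max: float, t_min: float = 0.0) -> np.ndarray:
    """First zero crossing of the field along ``start + t*direction``."""
    d = _unit(direction)
    ts = np.linspace(t_min, t_max, 256)
    vals = sdf(start[None, :] + ts[:, None] * d[None, :])
    sign = np.sign(vals)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(crossings) == 0:
        raise ShapeRejectionError("no surface crossing found for landmark ray")
    i = crossings[0]
    f = lambda t: float(sdf((start + t * d)[None, :])[0])
    t0 = brentq(f, ts[i], ts[i + 1], xtol=1e-8)
    return start + t0 * d


def _perpendicular(d: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(d, ref))


def build_atrium(params: ShapeParams, mesh_resolution: float = 1.0) -> AtriumShape:
    """Construct the watertight surface mesh and landmarks for ``params``.

    The mesh is extracted by marching cubes on the analytic field sampled
    at ``mesh_resolution`` mm, independent of any training grid.  Raises
    :class:`ShapeRejectionError` for degenerate parameter sets (callers
    are expected to resample).
    """
    params.validate()
    sdf = make_sdf(params)

    # generous canonical bounding box from primitive extents
    pts = [params.body_axes, -params.body_axes]
    for a, b, r in sdf.tubes:
        pts += [a - r, a + r, b - r, b + r]
    app_d, app_anchor = _unit(params.appendage_direction), None
    t_app = 1.0 / float(_body_radial(app_d[None, :], params.body_axes)[0])
    c = app_d * t_app
    pts += [c - params.appendage_size, c + params.appendage_size]
    pts = np.array(pts)
    pad = BLEND_WIDTH_MM + abs(params.bend) + 3 * mesh_resolution + 2.0
    lo, hi = pts.min(axis=0) - pad, pts.max(axis=0) + pad

    axes_samp = [np.arange(l, h + mesh_resolution, mesh_resolution)
                 for l, h in zip(lo, hi)]
    shape3 = tuple(len(a) for a in axes_samp)
    centers = np.stack(np.meshgrid(*axes_samp, indexing="ij"), axis=-1).reshape(-1, 3)
    vals = np.empty(len(centers))
    for i in range(0, len(centers), 500_000):
        vals[i : i + 500_000] = sdf(centers[i : i + 500_000])
    field3 = vals.reshape(shape3)
    if field3.min() > 0 or field3.max() < 0:
        raise ShapeRejectionError("field has no zero crossing")

    verts, faces, _, _ = measure.marching_cubes(
        field3, level=0.0, spacing=(mesh_resolution,) * 3
    )
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=True)
    if len(parts) == 0:
        raise ShapeRejectionError("marching cubes produced no watertight component")
    mesh = max(parts, key=lambda m: abs(m.volume))
    if not mesh.is_watertight:
        raise ShapeRejectionError("surface is not watertight")

    landmarks = {}
    for name in PV_NAMES:
        pv = params.pvs[name]
        d, anchor_c = _unit(pv.direction), None
        t_s = 1.0 / float(_body_radial(_unit(pv.direction)[None, :], params.body_axes)[0])
        anchor_w = _unwarp_point(d * t_s, params)
        u = _perpendicular(d)
        try:
            p = _surface_point_along(sdf, anchor_w, u, pv.radius + 4 * BLEND_WIDTH_MM + 10)
        except ShapeRejectionError:
            p = _surface_point_along(sdf, anchor_w, -u, pv.radius + 4 * BLEND_WIDTH_MM + 10)
        landmarks[f"ostium_{name}"] = p

    origin = np.zeros(3)
    landmarks["septum"] = _surface_point_along(
        sdf, origin, params.septum_direction, float(np.linalg.norm(hi - lo))
    )
    try:
        app_t_max = float(np.linalg.norm(hi - lo))
        crossings = _surface_point_along(sdf, origin, params.appendage_direction, app_t_max)
        landmarks["appendage"] = crossings
    except ShapeRejectionError:
        pass

    return AtriumShape(mesh=mesh, landmarks=LandmarkSet(landmarks), sdf=sdf,
                       params=params)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def points_in_mesh(mesh: trimesh.Trimesh, points: np.ndarray,
                   chunk: int = 2_000_000) -> np.ndarray:
    """Inside test via the generalized winding number (robust, exact-ish).

    Sums the signed solid angles of all triangles as seen from each query
    point; a winding number >= 1/2 marks the point as interior.  Works for
    watertight meshes regardless of near-degenerate triangles.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles  # (F, 3, 3)
    n_f = len(tri)
    out = np.empty(len(pts))
    pchunk = max(1, chunk // max(n_f, 1))
    for s in range(0, len(pts), pchunk):
        p = pts[s : s + pchunk]  # (P, 3)
        a = tri[None, :, 0, :] - p[:, None, :]  # (P, F, 3)
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        det = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("pfi,pfi->pf", a, b) * lc
            + np.einsum("pfi,pfi->pf", b, c) * la
            + np.einsum("pfi,pfi->pf", c, a) * lb
        )
        omega = 2.0 * np.arctan2(det, denom)  # signed solid angle per tri
        out[s : s + pchunk] = omega.sum(axis=1) / (4.0 * np.pi)
    return out >= 0.5


def voxelize_shape(shape: AtriumShape, grid: GridSpec) -> OccupancyVolume:
    """Binary occupancy: voxel = 1 iff its centre is inside or on the mesh."""
    lo = np.asarray(grid.origin) - grid.spacing / 2.0
    hi = lo + np.asarray(grid.dims) * grid.spacing
    bounds = shape.mesh.bounds
    for ax, name in enumerate("xyz"):
        if bounds[0, ax] < lo[ax] or bounds[1, ax] > hi[ax]:
            raise ValueError(
                f"mesh exceeds grid extent along axis {name}: "
                f"mesh [{bounds[0, ax]:.1f}, {bounds[1, ax]:.1f}] mm vs "
                f"grid [{lo[ax]:.1f}, {hi[ax]:.1f}] mm"
            )
    centers = grid.voxel_centers().reshape(-1, 3)
    inside = shape.contains(centers)
    return OccupancyVolume(grid=grid, values=inside.reshape(grid.dims).astype(np.uint8))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(
    n_train: int,
    n_test: int,
    model: ShapeModelSpec | None = None,
    grid: GridSpec | None = None,
    seed: int = 0,
    mesh_resolution: float = 1.5,
) -> tuple[list[tuple[AtriumShape, OccupancyVolume]], list[tuple[AtriumShape, OccupancyVolume]]]:
    """Sample plausibility-filtered atria with their occupancy volumes.

    Returns disjoint train and test lists, reproducible per seed.  Raises
    a configuration error if the plausibility filter accepts fewer than
    1% of draws.
    """
    if n_train < 0 or n_test < 0 or n_train + n_test == 0:
        raise ValueError("need a positive total number of samples")
    model = model if model is not None else default_shape_model()
    grid = grid if grid is not None else GridSpec()
    rng = np.random.default_rng(seed)
    accepted: list[tuple[AtriumShape, OccupancyVolume]] = []
    attempts = 0
    target = n_train + n_test
    while len(accepted) < target:
        attempts += 1
        if attempts > 100_000 or (attempts >= 2_000 and not accepted):
            raise ValueError(
                f"plausibility acceptance rate below 1% "
                f"({len(accepted)}/{attempts} accepted); check the shape model"
            )
        vec = model.sample_vector(rng)
        if model.mahalanobis(vec) > model.threshold:
            continue
        params = ShapeParams.from_vector(vec)
        try:
            params.validate()
            atrium = build_atrium(params, mesh_resolution=mesh_resolution)
            volume = voxelize_shape(atrium, grid)
        except (ShapeRejectionError, ValueError):
            continue
        if volume.count() == 0 or volume.n_components() != 1:
            continue
        accepted.append((atrium, volume))
    return accepted[:n_train], accepted[n_train : n_train + n_test]
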