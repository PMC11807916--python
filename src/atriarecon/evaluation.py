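"""Surface-distance evaluation of reconstructions against ground truth.

Reconstructed volumes become triangular meshes by marching cubes at the
0.5 level; accuracy is measured by symmetric nearest-vertex
surface-to-surface distances, optionally restricted to vertices within
a given radius of any of the four PV-ostium interest points (the
clinically critical regions), plus the Hausdorff distance and a paired
one-tailed t-test of improvement over the mean-shape baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import stats
from scipy.spatial import cKDTree
from skimage import measure

from .grid import OccupancyVolume, ProbabilityVolume
from .shapemodel import LandmarkSet

#: evaluation radii (mm) around PV interest points; None = unbounded
DEFAULT_RADII: tuple[float | None, ...] = (10.0, 15.0, 20.0, 25.0, None)


def extract_mesh(volume, iso: float = 0.5) -> trimesh.Trimesh:
    """Marching-cubes iso-surface in mm; largest connected component."""
    vals = np.asarray(volume.values, dtype=float)
    if vals.min() >= iso or vals.max() < iso:
        raise ValueError(f"volume has no crossing of iso level {iso}")
    grid = volume.grid
    verts, faces, _, _ = measure.marching_cubes(vals, level=iso)
    verts = verts * grid.spacing + np.asarray(grid.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda m: len(m.vertices))
    return mesh


@dataclass
class DistanceEntry:
    """One radius row of a per-case distance report."""

    radius_mm: float | None
    mean_mm: float
    std_mm: float
    n_vertices: int
    a_to_b_mm: float
    b_to_a_mm: float


@dataclass
class DistanceReport:
    """Per-case surface distances for all radii plus Hausdorff."""

    entries: dict[object, DistanceEntry] = field(default_factory=dict)
    hausdorff_mm: float = float("nan")

    def mean(self, radius) -> float:
        return self.entries[radius].mean_mm


def _directed(a_verts, b_tree, mask) -> np.ndarray:
    d, _ = b_tree.query(a_verts[mask])
    return d


def symmetric_surface_distance(
    a: trimesh.Trimesh,
    b: trimesh.Trimesh,
    interest_points: LandmarkSet | dict | None = None,
    radius: float | None = None,
) -> DistanceEntry:
    """Mean nearest-vertex distance averaged over both directions.

    With a finite ``radius``, only vertices within that distance of at
    least one PV interest point enter either direction (the union of
    balls around the four ostia).  Raises if the restriction leaves no
    vertices on either mesh.
    """
    if len(a.vertices) == 0 or len(b.vertices) == 0:
        raise ValueError("meshes must be nonempty")
    av, bv = np.asarray(a.vertices), np.asarray(b.vertices)
    if radius is None:
        mask_a = np.ones(len(av), dtype=bool)
        mask_b = np.ones(len(bv), dtype=bool)
    else:
        if interest_points is None:
            raise ValueError("a radius restriction needs interest points")
        pts = (interest_points.ostia() if isinstance(interest_points, LandmarkSet)
               else interest_points)
        centers = np.array(list(pts.values()))
        ctree = cKDTree(centers)
        mask_a = ctree.query(av)[0] <= radius
        mask_b = ctree.query(bv)[0] <= radius
        if not mask_a.any() or not mask_b.any():
            raise ValueError(
                f"no vertices within {radius} mm of the interest points"
            )
    atree, btree = cKDTree(av), cKDTree(bv)
    d_ab = _directed(av, btree, mask_a)
    d_ba = _directed(bv, atree, mask_b)
    mean_ab, mean_ba = float(d_ab.mean()), float(d_ba.mean())
    both = np.concatenate([d_ab, d_ba])
    return DistanceEntry(
        radius_mm=radius,
        mean_mm=0.5 * (mean_ab + mean_ba),
        std_mm=float(both.std()),
        n_vertices=int(mask_a.sum() + mask_b.sum()),
        a_to_b_mm=mean_ab,
        b_to_a_mm=mean_ba,
    )


def hausdorff(a: trimesh.Trimesh, b: trimesh.Trimesh) -> float:
    """Max over both directions of the maximal nearest-vertex distance."""
    av, bv = np.asarray(a.vertices), np.asarray(b.vertices)
    if len(av) == 0 or len(bv) == 0:
        raise ValueError("meshes must be nonempty")
    d_ab = cKDTree(bv).query(av)[0].max()
    d_ba = cKDTree(av).query(bv)[0].max()
    return float(max(d_ab, d_ba))


def paired_one_tailed_ttest(method_errors, baseline_errors) -> float:
    """P-value for "the method improves on the baseline".

    Tests mean(baseline - method) > 0 with the exact Student-t tail on
    the paired differences.  Zero-variance differences degenerate to
    p = 0.5 (identical), 0 (uniform improvement) or 1 (uniform harm).
    """
    m = np.asarray(method_errors, dtype=float)
    b = np.asarray(baseline_errors, dtype=float)
    if m.shape != b.shape or m.ndim != 1 or len(m) < 2:
        raise ValueError("need two equal-length error lists with >= 2 cases")
    d = b - m
    sd = d.std(ddof=1)
    if sd == 0.0:
        mu = d.mean()
        return 0.5 if mu == 0 else (0.0 if mu > 0 else 1.0)
    t = d.mean() / (sd / math.sqrt(len(d)))
    return float(stats.t.sf(t, df=len(d) - 1))


def report_distances(
    recon_mesh: trimesh.Trimesh,
    gt_mesh: trimesh.Trimesh,
    interest_points,
    radii=DEFAULT_RADII,
) -> DistanceReport:
    rep = DistanceReport()
    for r in radii:
        rep.entries[r] = symmetric_surface_distance(
            recon_mesh, gt_mesh, interest_points, r
        )
    rep.hausdorff_mm = hausdorff(recon_mesh, gt_mesh)
    return rep


def evaluate_benchmark(
    reconstructions: dict[str, list],
    ground_truths: list,
    landmark_sets: list[LandmarkSet],
    radii=DEFAULT_RADII,
    baseline_method: str = "mean_shape",
) -> pd.DataFrame:
    """Per-method, per-radius summary across matched cases.

    ``reconstructions`` maps method name -> list of meshes or volumes
    (one per case, matched to ``ground_truths``).  Output columns:
    method, radius_mm, mean_mm, std_mm, p_value (vs the baseline
    method, paired one-tailed), hausdorff_mm.
    """
    n_cases = len(ground_truths)
    for name, rs in reconstructions.items():
        if len(rs) != n_cases:
            raise ValueError(
                f"method {name} has {len(rs)} cases, expected {n_cases}"
            )
    if len(landmark_sets) != n_cases:
        raise ValueError("landmark sets must match the case count")

    def as_mesh(obj):
        if isinstance(obj, trimesh.Trimesh):
            return obj
        return extract_mesh(obj)

    gt_meshes = [as_mesh(g) for g in ground_truths]
    per_case: dict[str, dict] = {}
    hd: dict[str, list] = {}
    for name, rs in reconstructions.items():
        per_case[name] = {r: [] for r in radii}
        hd[name] = []
        for rec, gt, lms in zip(rs, gt_meshes, landmark_sets):
            mesh = as_mesh(rec)
            for r in radii:
                per_case[name][r].append(
                    symmetric_surface_distance(mesh, gt, lms, r).mean_mm
                )
            hd[name].append(hausdorff(mesh, gt))

    rows = []
    for name in reconstructions:
        for r in radii:
            errs = np.asarray(per_case[name][r])
            if baseline_method in per_case and name != baseline_method:
                p = paired_one_tailed_ttest(errs, per_case[baseline_method][r])
            elif name == baseline_method:
                p = 0.5
            else:
                p = float("nan")
            rows.append({
                "method": name,
                "radius_mm": np.inf if r is None else r,
                "mean_mm": errs.mean(),
                "std_mm": errs.std(),
                "p_value": p,
                "hausdorff_mm": float(np.mean(hd[name])),
            })
    return pd.DataFrame(rows)
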