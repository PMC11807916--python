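"""Catheter-path simulation inside synthetic atria.

Emulates the initial-bearing manoeuvre: the catheter enters at the
trans-septal puncture and visits the four pulmonary-vein ostia in the
clinical order left-superior, left-inferior, right-inferior,
right-superior.  Each leg is a least-cost route on the graph of interior
voxels, where edge costs mix geometric length with a navigability
penalty that discourages hugging the chamber wall — so simulated paths
curve toward the atrium centre before turning to the next target, like
real catheters do.  A stochastic augmentation stage then scatters points
around the path to model sensor jitter and wall pushing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from scipy.spatial import cKDTree

from .grid import GridSpec, OccupancyVolume
from .shapemodel import PV_NAMES, AtriumShape, LandmarkSet

logger = logging.getLogger(__name__)

#: traversal legs in clinical order
SEGMENTS: tuple[str, ...] = (
    "septum-PVLS",
    "PVLS-PVLI",
    "PVLI-PVRI",
    "PVRI-PVRS",
)
AUGMENTATION_LABEL = "augmentation"

#: default weight of the navigability term in the edge cost
DEFAULT_NAVIGABILITY_WEIGHT = 2.0


class NoPathError(RuntimeError):
    """Raised when a requested leg cannot be routed."""


@dataclass
class PathPointCloud:
    """Ordered catheter positions in mm with per-point segment labels."""

    points: np.ndarray  # (n, 3) mm
    labels: np.ndarray  # (n,) str
    source_shape_id: str | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        if self.points.shape[0] != self.labels.shape[0]:
            raise ValueError("points and labels must have equal length")
        if self.points.shape[0] < 2:
            raise ValueError("a path needs at least 2 points")

    def __len__(self) -> int:
        return self.points.shape[0]

    def non_augmented(self) -> "PathPointCloud":
        keep = self.labels != AUGMENTATION_LABEL
        return PathPointCloud(self.points[keep], self.labels[keep],
                              self.source_shape_id)


@dataclass
class AugmentationConfig:
    """Stochastic scatter around the raw path.

    ``n`` Gaussian samples (std ``sigma`` mm) are drawn around every path
    point, kept independently with probability ``s_f``, filtered to the
    chamber interior, and finally jittered by N(0, I) * ``mu_s`` mm — the
    jitter is applied after the interior filter, so augmented clouds may
    slightly exit the chamber, as real catheters push the wall.
    """

    n: int = 5
    sigma: float = 2.0
    s_f: float = 0.5
    mu_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.sigma < 0 or self.mu_s < 0:
            raise ValueError("sigma and mu_s must be >= 0")
        if not 0.0 <= self.s_f <= 1.0:
            raise ValueError("s_f must lie in [0, 1]")


@dataclass
class TraversalGraph:
    """26-connected graph over interior voxels with navigability costs."""

    grid: GridSpec
    node_voxels: np.ndarray  # (m, 3) int voxel indices, lexicographic order
    adjacency: sparse.csr_matrix = field(repr=False)  # (m, m) positive costs
    wall_distance_mm: np.ndarray = field(repr=False)  # (m,)
    _flat_to_node: dict = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._flat_to_node is None:
            dims = self.grid.dims
            flat = np.ravel_multi_index(self.node_voxels.T, dims)
            self._flat_to_node = {int(f): i for i, f in enumerate(flat)}

    def node_of(self, voxel) -> int:
        try:
            flat = int(np.ravel_multi_index(tuple(int(c) for c in voxel),
                                            self.grid.dims))
        except ValueError:
            raise KeyError(f"voxel {tuple(voxel)} lies outside the grid") from None
        if flat not in self._flat_to_node:
            raise KeyError(f"voxel {tuple(voxel)} is not an interior graph node")
        return self._flat_to_node[flat]


_OFFSETS26 = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) != (0, 0, 0)]
)


def build_traversal_graph(
    volume: OccupancyVolume,
    navigability_weight: float = DEFAULT_NAVIGABILITY_WEIGHT,
) -> TraversalGraph:
    """Edge cost = Euclidean step length * (1 + w / (1 + d_wall)).

    ``d_wall`` is the mm distance of the edge midpoint to the nearest
    non-interior voxel (approximated as the mean of the two endpoint
    wall distances).  With w = 0 the graph reduces to pure geometric
    length; larger w makes wall-adjacent steps costlier.
    """
    occ = volume.values.astype(bool)
    if not occ.any():
        raise ValueError("volume has no interior voxels")
    struct26 = ndimage.generate_binary_structure(3, 3)
    labels, n_comp = ndimage.label(occ, structure=struct26)
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        raise ValueError(
            f"interior is disconnected: {n_comp} components with sizes "
            f"{sorted(sizes.tolist(), reverse=True)}"
        )
    spacing = volume.grid.spacing
    dwall_vox = ndimage.distance_transform_edt(occ)  # voxels to nearest 0
    dwall_mm = dwall_vox * spacing

    nodes = np.argwhere(occ)  # lexicographic by construction
    dims = volume.grid.dims
    flat = np.ravel_multi_index(nodes.T, dims)
    node_id = -np.ones(int(np.prod(dims)), dtype=np.int64)
    node_id[flat] = np.arange(len(nodes))
    dvals = dwall_mm[occ]

    rows, cols, costs = [], [], []
    half = _OFFSETS26[: len(_OFFSETS26) // 2]  # one direction per pair
    for off in half:
        nb = nodes + off
        ok = np.all((nb >= 0) & (nb < np.asarray(dims)), axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, dims)
        j = node_id[nb_flat]
        valid = j >= 0
        i = np.nonzero(ok)[0][valid]
        j = j[valid]
        step = np.linalg.norm(off) * spacing
        dmid = 0.5 * (dvals[i] + dvals[j])
        c = step * (1.0 + navigability_weight / (1.0 + dmid))
        rows.append(i)
        cols.append(j)
        costs.append(c)
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    c = np.concatenate(costs)
    m = len(nodes)
    adj = sparse.coo_matrix(
        (np.concatenate([c, c]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(m, m),
    ).tocsr()
    return TraversalGraph(grid=volume.grid, node_voxels=nodes, adjacency=adj,
                          wall_distance_mm=dvals)


def shortest_path(graph: TraversalGraph, src, dst) -> tuple[np.ndarray, float]:
    """Minimal-cost voxel path from ``src`` to ``dst`` (inclusive).

    Distances come from Dijkstra on the sparse graph; the path itself is
    reconstructed by walking back from the destination, always choosing
    the lexicographically smallest voxel among optimal predecessors, so
    ties break deterministically.  Returns (voxel index array (L, 3),
    total cost).
    """
    s = graph.node_of(src)
    t = graph.node_of(dst)
    if s == t:
        return graph.node_voxels[[s]].copy(), 0.0
    dist = _csgraph_dijkstra(graph.adjacency, directed=False, indices=s)
    if not np.isfinite(dist[t]):
        raise NoPathError(f"no route from voxel {tuple(src)} to {tuple(dst)}")
    adj = graph.adjacency
    path = [t]
    cur = t
    while cur != s:
        lo, hi = adj.indptr[cur], adj.indptr[cur + 1]
        nbrs = adj.indices[lo:hi]
        w = adj.data[lo:hi]
        ok = np.isclose(dist[nbrs] + w, dist[cur], rtol=1e-10, atol=1e-9)
        cands = nbrs[ok]
        if len(cands) == 0:  # numerical safety net
            cands = nbrs[np.argmin(dist[nbrs] + w - dist[cur])][None]
        cur = int(cands.min())  # node ids are lexicographic in voxel index
        path.append(cur)
    path.reverse()
    return graph.node_voxels[path].copy(), float(dist[t])


def locate_ostia_entries(shape: AtriumShape, volume: OccupancyVolume) -> LandmarkSet:
    """Snap each landmark to the nearest interior voxel centre.

    Errors if a landmark has no interior voxel within 3 voxel spacings
    (the voxelization then cannot represent that ostium).
    """
    occ = volume.values.astype(bool)
    centers = volume.grid.voxel_centers()[occ]
    tree = cKDTree(centers)
    out = {}
    names = ["septum"] + [f"ostium_{p}" for p in PV_NAMES]
    for name in names:
        d, i = tree.query(shape.landmarks[name])
        if d > 3 * volume.grid.spacing:
            raise ValueError(
                f"no interior voxel within 3 spacings of landmark {name} "
                f"(nearest at {d:.2f} mm)"
            )
        out[name] = centers[i]
    return LandmarkSet(points=out)


def compose_path(
    shape: AtriumShape,
    volume: OccupancyVolume,
    navigability_weight: float = DEFAULT_NAVIGABILITY_WEIGHT,
    source_shape_id: str | None = None,
) -> PathPointCloud:
    """Route septum -> PVLS -> PVLI -> PVRI -> PVRS through the interior."""
    entries = locate_ostia_entries(shape, volume)
    graph = build_traversal_graph(volume, navigability_weight)
    grid = volume.grid
    order = ["septum", "ostium_PVLS", "ostium_PVLI", "ostium_PVRI", "ostium_PVRS"]
    stops = [np.rint(grid.world_to_index(entries[n])).astype(int) for n in order]
    points: list[np.ndarray] = []
    labels: list[str] = []
    for leg, (a, b) in zip(SEGMENTS, zip(stops[:-1], stops[1:])):
        try:
            vox, _ = shortest_path(graph, a, b)
        except NoPathError as e:
            raise NoPathError(f"leg {leg} is unreachable: {e}") from e
        mm = grid.index_to_world(vox)
        if points:  # junction voxel already emitted by the previous leg
            mm = mm[1:]
        points.append(mm)
        labels.extend([leg] * len(mm))
    return PathPointCloud(np.concatenate(points, axis=0), np.array(labels, dtype=object),
                          source_shape_id)


def augment_path(
    path: PathPointCloud, shape: AtriumShape, cfg: AugmentationConfig
) -> PathPointCloud:
    """Scatter points around the path (see :class:`AugmentationConfig`).

    Original points are retained; augmentation points are appended with
    the ``augmentation`` label.  Deterministic per ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n == 0 or cfg.s_f == 0.0:
        # draw nothing; output equals input
        return PathPointCloud(path.points.copy(), path.labels.copy(),
                              path.source_shape_id)
    base = path.points
    samples = rng.normal(loc=base[:, None, :], scale=cfg.sigma,
                         size=(len(base), cfg.n, 3)).reshape(-1, 3)
    keep = rng.random(len(samples)) < cfg.s_f
    samples = samples[keep]
    if len(samples):
        samples = samples[shape.contains(samples)]
    if len(samples):
        samples = samples + rng.standard_normal(samples.shape) * cfg.mu_s
    pts = np.concatenate([base, samples], axis=0)
    labels = np.concatenate(
        [path.labels, np.array([AUGMENTATION_LABEL] * len(samples), dtype=object)]
    )
    return PathPointCloud(pts, labels, path.source_shape_id)


def path_to_volume(path: PathPointCloud, grid: GridSpec) -> OccupancyVolume:
    """Bin path points to voxels: 1 iff at least one point lands in the voxel."""
    idx = np.rint(grid.world_to_index(path.points)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(grid.dims)), axis=1)
    n_out = int((~inside).sum())
    if n_out == len(idx):
        raise ValueError("all path points fall outside the grid")
    if n_out:
        logger.warning("path_to_volume: clipped %d points outside the grid", n_out)
    vals = np.zeros(grid.dims, dtype=np.uint8)
    vals[tuple(idx[inside].T)] = 1
    return OccupancyVolume(grid=grid, values=vals)
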