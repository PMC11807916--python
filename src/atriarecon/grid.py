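"""Voxel grids and occupancy volumes.

The reconstruction pipeline works on a fixed cubic voxel grid (default
45^3 voxels at 2.666 mm edge length, i.e. a ~120 mm cube centred on the
origin, enough to contain a human left atrium).  An *occupancy volume*
marks chamber interior/boundary voxels with 1 and everything else with 0;
a *probability volume* holds per-voxel interior probabilities produced by
a network's sigmoid output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: 6-connectivity structuring element (faces only).
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular voxel grid.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each axis.
    spacing : float
        Voxel edge length in mm.
    origin : tuple of float, optional
        World (mm) coordinates of the centre of voxel (0, 0, 0).  By
        default the grid is centred on the world origin.
    """

    dims: tuple[int, int, int] = (45, 45, 45)
    spacing: float = 2.666
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if not np.isfinite(self.spacing) or self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "dims", dims)
        if self.origin is None:
            ori = tuple(-(d - 1) / 2.0 * self.spacing for d in dims)
        else:
            ori = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "origin", ori)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical edge lengths of the grid box (mm)."""
        return np.asarray(self.dims) * self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to mm coordinates of voxel centres."""
        return np.asarray(idx, dtype=float) * self.spacing + np.asarray(self.origin)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map mm coordinates to fractional voxel indices."""
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / self.spacing

    def voxel_centers(self) -> np.ndarray:
        """All voxel-centre coordinates, shape (*dims, 3), in mm."""
        axes = [np.arange(d) * self.spacing + o for d, o in zip(self.dims, self.origin)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        return grid

    def contains_points(self, xyz: np.ndarray) -> np.ndarray:
        """Whether each mm point rounds to a voxel index inside the grid."""
        idx = np.rint(self.world_to_index(xyz)).astype(int)
        return np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=-1)


@dataclass
class OccupancyVolume:
    """Binary interior/boundary indicator over a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != self.grid.dims:
            raise ValueError(
                f"values shape {vals.shape} does not match grid dims {self.grid.dims}"
            )
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("occupancy values must be binary (0/1)")
        self.values = vals.astype(np.uint8)

    def boundary(self) -> np.ndarray:
        """Occupied voxels with at least one empty 6-neighbour (bool array)."""
        occ = self.values.astype(bool)
        eroded = ndimage.binary_erosion(occ, structure=_STRUCT6, border_value=0)
        return occ & ~eroded

    def n_components(self, connectivity: int = 1) -> int:
        """Number of connected occupied components (6-connected by default)."""
        struct = ndimage.generate_binary_structure(3, connectivity)
        _, n = ndimage.label(self.values, structure=struct)
        return int(n)

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class ProbabilityVolume:
    """Per-voxel interior probability in [0, 1]."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != self.grid.dims:
            raise ValueError(
                f"values shape {vals.shape} does not match grid dims {self.grid.dims}"
            )
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.values = vals


def binarize(
    x: ProbabilityVolume | OccupancyVolume, threshold: float = 0.5
) -> OccupancyVolume:
    """Threshold a probability volume: voxel = 1 iff value >= threshold.

    The >= convention makes an all-0.5 volume fully occupied; the map is
    idempotent and monotone (raising the threshold never adds voxels).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    vals = (np.asarray(x.values, dtype=float) >= threshold).astype(np.uint8)
    return OccupancyVolume(grid=x.grid, values=vals)
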