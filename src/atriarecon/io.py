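"""Shared I/O: NIfTI volumes, point-cloud CSV/PLY, landmarks, checkpoints.

Volumes are stored as NIfTI (.nii.gz) with voxel spacing and origin in
the affine (binary occupancy as uint8, probability as float32); point
clouds as CSV with columns x_mm, y_mm, z_mm, segment (or PLY, which
drops the segment column); landmarks as JSON {name: [x, y, z]} in mm;
model checkpoints as a single .npz with a YAML config block and the
parameter tensors in deterministic order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh
import yaml

from .grid import GridSpec, OccupancyVolume, ProbabilityVolume
from .paths import PathPointCloud
from .shapemodel import LandmarkSet


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def write_volume(volume, path) -> None:
    grid = volume.grid
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = grid.spacing
    affine[:3, 3] = grid.origin
    if isinstance(volume, OccupancyVolume):
        data = volume.values.astype(np.uint8)
    else:
        data = volume.values.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume(path, expected_grid: GridSpec | None = None):
    """Load a volume; refuses silently resampling mismatched grids."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    affine = img.affine
    spacing = float(affine[0, 0])
    origin = tuple(float(v) for v in affine[:3, 3])
    grid = GridSpec(dims=data.shape, spacing=spacing, origin=origin)
    if expected_grid is not None:
        if tuple(data.shape) != tuple(expected_grid.dims):
            raise ValueError(
                f"volume shape {data.shape} does not match expected dims "
                f"{expected_grid.dims}"
            )
        if not np.isclose(spacing, expected_grid.spacing):
            raise ValueError(
                f"voxel spacing {spacing} mm differs from expected "
                f"{expected_grid.spacing} mm; refusing to resample"
            )
    uniq = np.unique(data)
    if np.issubdtype(data.dtype, np.integer) and np.all(np.isin(uniq, (0, 1))):
        return OccupancyVolume(grid=grid, values=data.astype(np.uint8))
    return ProbabilityVolume(grid=grid, values=data.astype(np.float64))


# ---------------------------------------------------------------------------
# point clouds and landmarks
# ---------------------------------------------------------------------------


def write_cloud(cloud: PathPointCloud, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        trimesh.PointCloud(cloud.points).export(str(path))
        return
    df = pd.DataFrame(cloud.points, columns=["x_mm", "y_mm", "z_mm"])
    df["segment"] = cloud.labels
    df.to_csv(path, index=False)


def read_cloud(path) -> PathPointCloud:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        pc = trimesh.load(str(path))
        pts = np.asarray(pc.vertices)
        if len(pts) == 0:
            raise ValueError(f"{path} contains no points")
        labels = np.array(["unknown"] * len(pts), dtype=object)
        return PathPointCloud(pts, labels)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path} contains no points")
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if "segment" in df.columns:
        labels = df["segment"].astype(str).to_numpy(dtype=object)
    else:
        labels = np.array(["unknown"] * len(pts), dtype=object)
    return PathPointCloud(pts, labels)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(json.dumps(
        {k: [float(x) for x in v] for k, v in landmarks.points.items()}, indent=1
    ))


def read_landmarks(path) -> LandmarkSet:
    data = json.loads(Path(path).read_text())
    return LandmarkSet({k: np.asarray(v, dtype=float) for k, v in data.items()})


def read_tagged_points(path) -> dict[str, np.ndarray]:
    data = json.loads(Path(path).read_text())
    return {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in data.items()}


# ---------------------------------------------------------------------------
# configs and checkpoints
# ---------------------------------------------------------------------------


def _grid_to_dict(g: GridSpec) -> dict:
    return {"dims": list(g.dims), "spacing": g.spacing, "origin": list(g.origin)}


def _grid_from_dict(d: dict) -> GridSpec:
    return GridSpec(dims=tuple(d["dims"]), spacing=d["spacing"],
                    origin=tuple(d["origin"]))


def config_to_dict(cfg) -> dict:
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, GridSpec):
            v = _grid_to_dict(v)
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def config_from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(d)
    for f in dataclasses.fields(cls):
        if f.name in kwargs:
            if f.name == "grid":
                kwargs[f.name] = _grid_from_dict(kwargs[f.name])
            elif isinstance(f.default, tuple) and isinstance(kwargs[f.name], list):
                kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def _model_state(model) -> list[np.ndarray]:
    arrays = [p.value for p in model.params()]
    for attr in vars(model).values():
        if hasattr(attr, "running_mean"):
            arrays += [attr.running_mean, attr.running_var]
    # nested blocks (V-Net)
    for name in ("enc", "dec"):
        for blk in getattr(model, name, []):
            arrays += [blk.bn.running_mean, blk.bn.running_var]
    if hasattr(model, "bottom"):
        arrays += [model.bottom.bn.running_mean, model.bottom.bn.running_var]
    return arrays


def save_checkpoint(model, path, history=None) -> None:
    from .ded import DED
    kind = "ded" if isinstance(model, DED) else "vnet"
    cfg_yaml = yaml.safe_dump({"kind": kind, "config": config_to_dict(model.cfg)})
    arrays = {f"a{i}": a for i, a in enumerate(_model_state(model))}
    if history is not None:
        arrays["history"] = np.array(
            [history.epoch, history.loss, history.bce, history.dice, history.swr]
        )
    np.savez_compressed(path, config=np.frombuffer(cfg_yaml.encode(), dtype=np.uint8),
                        **arrays)


def load_checkpoint(path):
    from .ded import DED, DEDConfig
    from .vnet import VNet, VNetConfig
    data = np.load(path, allow_pickle=False)
    meta = yaml.safe_load(bytes(data["config"]).decode())
    if meta["kind"] == "ded":
        model = DED(config_from_dict(DEDConfig, meta["config"]))
    else:
        model = VNet(config_from_dict(VNetConfig, meta["config"]))
    state = _model_state(model)
    for i, arr in enumerate(state):
        arr[...] = data[f"a{i}"]
    return model


def history_to_csv(history, path) -> None:
    pd.DataFrame({
        "epoch": history.epoch,
        "loss": history.loss,
        "bce": history.bce,
        "dice": history.dice,
        "swr": history.swr,
        "val_dice": history.val_dice,
    }).to_csv(path, index=False)
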