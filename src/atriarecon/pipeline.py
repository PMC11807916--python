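"""End-to-end workflow: generate shapes, simulate paths, train, evaluate.

One :class:`RunConfig` drives the whole synthetic-training workflow;
every stage writes its artifacts (plus a manifest with the config hash
and seeds) under the run directory, and the stages can be re-run
individually through the CLI.  All randomness derives from the single
run seed, so a rerun with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as aio
from .ded import DED, DEDConfig, SWR_VARIANTS, train_ded
from .evaluation import DEFAULT_RADII, evaluate_benchmark, extract_mesh
from .grid import GridSpec, OccupancyVolume
from .paths import AugmentationConfig, augment_path, compose_path, path_to_volume
from .registration import compute_mean_shape
from .shapemodel import AtriumShape, default_shape_model, generate_dataset
from .vnet import VNetConfig, train_vnet

logger = logging.getLogger(__name__)


def derive_seed(base: int, *salt: int) -> int:
    """A reproducible child seed below 2**31."""
    return int(np.random.SeedSequence([base, *salt]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one synthetic train/evaluate run."""

    grid: GridSpec = field(default_factory=GridSpec)
    n_train: int = 200
    n_test: int = 50
    mesh_resolution: float = 1.5
    navigability_weight: float = 2.0
    augmentation_n: int = 5
    augmentation_sigma: float = 2.0
    augmentation_s_f: float = 0.5
    augmentation_mu_s: float = 1.0
    model: str = "ded"  # "ded" | "vnet"
    variant: str = "swr005"  # noswr | swr005 | swr75 | noaug (DED only)
    hidden: tuple[int, int] = (350, 350)
    epochs: int = 100
    batch_size: int = 20
    learning_rate: float = 1e-3
    radii: tuple = DEFAULT_RADII
    seed: int = 0
    out_dir: str = "runs/run0"

    def __post_init__(self) -> None:
        if self.model not in ("ded", "vnet"):
            raise ValueError("model must be 'ded' or 'vnet'")
        if self.model == "ded" and self.variant not in (*SWR_VARIANTS, "noaug"):
            raise ValueError(f"unknown DED variant {self.variant!r}")

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(aio.config_to_dict(self)).encode()
        ).hexdigest()[:16]


def build_inputs(
    dataset: list[tuple[AtriumShape, OccupancyVolume]],
    cfg: RunConfig,
    split_salt: int,
) -> list[tuple[OccupancyVolume, OccupancyVolume]]:
    """Simulate a catheter path per shape and voxelize it to a network input."""
    pairs = []
    augment = cfg.variant != "noaug"
    for i, (shape, volume) in enumerate(dataset):
        path = compose_path(shape, volume, cfg.navigability_weight,
                            source_shape_id=f"{split_salt}-{i}")
        if augment:
            acfg = AugmentationConfig(
                n=cfg.augmentation_n, sigma=cfg.augmentation_sigma,
                s_f=cfg.augmentation_s_f, mu_s=cfg.augmentation_mu_s,
                seed=derive_seed(cfg.seed, split_salt, i),
            )
            path = augment_path(path, shape, acfg)
        pairs.append((path_to_volume(path, cfg.grid), volume))
    return pairs


def make_model_config(cfg: RunConfig):
    if cfg.model == "vnet":
        stages = 4 if min(cfg.grid.dims) >= 32 else 3
        return VNetConfig(
            grid=cfg.grid, stages=stages, alpha=0.4,
            learning_rate=cfg.learning_rate, batch_size=min(cfg.batch_size, 8),
            epochs=cfg.epochs, seed=derive_seed(cfg.seed, 7),
        )
    lam = SWR_VARIANTS.get(cfg.variant, SWR_VARIANTS["swr005"])
    return DEDConfig(
        grid=cfg.grid, hidden=cfg.hidden, lambda_swr=lam,
        use_boundary_mask=cfg.variant != "noaug",
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        epochs=cfg.epochs, seed=derive_seed(cfg.seed, 7),
        dtype="float32",  # single precision is ample for training at scale
    )


def run_pipeline(cfg: RunConfig, write_artifacts: bool = True):
    """Execute generate -> paths -> train -> reconstruct -> evaluate.

    Returns (results DataFrame, dict of in-memory artifacts).  With
    ``write_artifacts`` the run directory receives volumes, meshes,
    checkpoints, the results CSV and a provenance manifest.
    """
    out = Path(cfg.out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}

    def stage(name):
        manifest["stages"][name] = {"seed": derive_seed(cfg.seed, hash(name) % 1000)}
        logger.info("stage %s", name)

    try:
        stage("generate-shapes")
        train_shapes, test_shapes = generate_dataset(
            cfg.n_train, cfg.n_test, default_shape_model(), cfg.grid,
            seed=derive_seed(cfg.seed, 1), mesh_resolution=cfg.mesh_resolution,
        )

        stage("generate-paths")
        train_pairs = build_inputs(train_shapes, cfg, split_salt=1)
        test_pairs = build_inputs(test_shapes, cfg, split_salt=2)

        stage("train")
        mcfg = make_model_config(cfg)
        if cfg.model == "vnet":
            model, hist = train_vnet(train_pairs, test_pairs, mcfg)
        else:
            model, hist = train_ded(train_pairs, test_pairs, mcfg)

        stage("reconstruct")
        recon_meshes = [
            extract_mesh(model.predict(x)) for x, _ in test_pairs
        ]
        gt_meshes = [extract_mesh(z) for _, z in test_pairs]
        landmark_sets = [s.landmarks for s, _ in test_shapes]

        stage("evaluate")
        mean_shape = compute_mean_shape(
            [v for _, v in train_shapes], [s.landmarks for s, _ in train_shapes]
        )
        mean_mesh = extract_mesh(mean_shape.binarized())
        method_name = f"{cfg.model}_{cfg.variant}" if cfg.model == "ded" else "vnet"
        results = evaluate_benchmark(
            {method_name: recon_meshes, "mean_shape": [mean_mesh] * len(gt_meshes)},
            gt_meshes, landmark_sets, radii=cfg.radii,
        )
    except Exception as e:
        raise RuntimeError(f"pipeline stage failed: {e}") from e

    artifacts = {
        "model": model, "history": hist, "mean_shape": mean_shape,
        "train_pairs": train_pairs, "test_pairs": test_pairs,
        "test_shapes": test_shapes, "recon_meshes": recon_meshes,
        "gt_meshes": gt_meshes, "results": results,
    }
    if write_artifacts:
        (out / "shapes").mkdir(exist_ok=True)
        for i, (s, v) in enumerate(test_shapes):
            aio.write_volume(v, out / "shapes" / f"test_{i:03d}_gt.nii.gz")
            aio.write_landmarks(s.landmarks, out / "shapes" / f"test_{i:03d}_landmarks.json")
        aio.save_checkpoint(model, out / "checkpoint.npz", hist)
        aio.history_to_csv(hist, out / "history.csv")
        aio.write_volume(mean_shape.binarized(), out / "mean_shape.nii.gz")
        results.to_csv(out / "results.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results, artifacts
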