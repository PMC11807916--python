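"""Shared fixtures: small synthetic shapes, toy datasets, benchmark run."""

from __future__ import annotations

import numpy as np
import pytest

from atriarecon import (
    DEDConfig,
    GridSpec,
    OccupancyVolume,
    default_shape_model,
    generate_dataset,
    train_ded,
)
from atriarecon.nn.losses import dice
from atriarecon.pipeline import RunConfig, run_pipeline

#: coarse grid used for fast shape/path tests (same 120 mm physical extent)
COARSE_GRID = GridSpec(dims=(24, 24, 24), spacing=5.0)


@pytest.fixture(scope="session")
def shape_model():
    return default_shape_model()


@pytest.fixture(scope="session")
def small_dataset(shape_model):
    """Ten generated atria with occupancy volumes on the coarse grid."""
    train, test = generate_dataset(
        8, 2, shape_model, COARSE_GRID, seed=42, mesh_resolution=2.5
    )
    return train + test


@pytest.fixture(scope="session")
def one_shape(small_dataset):
    return small_dataset[0]


def make_ellipsoid_toy(n: int = 50, seed: int = 0, n_input_points: int = 15):
    """Random-ellipsoid (input, target) volume pairs on a 12^3 grid."""
    g = GridSpec(dims=(12, 12, 12), spacing=2.0)
    rng = np.random.default_rng(seed)
    c = g.voxel_centers()
    pairs = []
    for _ in range(n):
        ax = rng.uniform(5, 9, 3)
        ctr = rng.uniform(-2, 2, 3)
        inside = (((c - ctr) / ax) ** 2).sum(-1) <= 1
        iv = np.argwhere(inside)
        sel = iv[rng.choice(len(iv), n_input_points)]
        xv = np.zeros(g.dims, np.uint8)
        xv[tuple(sel.T)] = 1
        pairs.append(
            (OccupancyVolume(g, xv), OccupancyVolume(g, inside.astype(np.uint8)))
        )
    return g, pairs


@pytest.fixture(scope="session")
def toy_problem():
    return make_ellipsoid_toy()


@pytest.fixture(scope="session")
def benchmark_run():
    """Scaled-down benchmark: 24^3 grid, 200 train / 50 test synthetic atria.

    Shared by the acceptance tests; one full DED (SWR005) training run.
    """
    cfg = RunConfig(
        grid=COARSE_GRID, n_train=200, n_test=50, mesh_resolution=2.5,
        epochs=200, hidden=(350, 350), variant="swr005", seed=1,
        out_dir="scratch/test_benchmark",
    )
    results, artifacts = run_pipeline(cfg, write_artifacts=False)
    model = artifacts["model"]
    dices = [dice(model.predict(x), z) for x, z in artifacts["test_pairs"]]
    artifacts["test_dices"] = np.asarray(dices)
    return cfg, results, artifacts
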