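"""Dense encoder-decoder (DED) for occupancy-volume reconstruction.

A multilayer perceptron over flattened occupancy volumes:

    N -> k -> k -> N,   N = number of voxels, k = hidden width (350),

with the input and output layers sharing one weight matrix (the output
map is the transpose of the input map — "tied weights", maintained as a
single stored matrix so the invariant holds after every optimizer
step).  The input is multiplied by a Bernoulli keep mask during
training (denoising-autoencoder style, no rescaling since the inputs
are binary indicators); hidden layers use batch normalization and ReLU;
the output layer a sigmoid.  Training minimizes the BCE/weighted-DICE
mix plus the spatial weight-smoothing regularizer on the tied matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, OccupancyVolume, ProbabilityVolume, binarize
from .nn.core import Adam, BatchNorm, Param, relu, sigmoid
from .nn.losses import (
    boundary_mask,
    loss_and_grad,
    swr_grad_accumulate,
    swr_penalty,
)

__all__ = ["DEDConfig", "DED", "TrainHistory", "train_ded", "binarize"]

#: named regularization variants (smoothing strength lambda)
SWR_VARIANTS = {"noswr": 0.0, "swr005": 0.05, "swr75": 75.0}


@dataclass
class DEDConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    hidden: tuple[int, int] = (350, 350)
    alpha: float = 0.4  # BCE weight in the loss mix (2/5)
    lambda_swr: float = 0.0
    beta_mask: float = 14.0
    sigma_mask: float = 1.5
    mask_mode: str = "peaked"
    use_boundary_mask: bool = True
    input_mask_rate: float = 0.3
    dice_squared: bool = False
    learning_rate: float = 1e-3
    batch_size: int = 20
    epochs: int = 300
    seed: int = 0
    dtype: str = "float64"  # "float32" halves memory traffic at scale

    def __post_init__(self) -> None:
        if len(self.hidden) != 2 or any(h <= 0 for h in self.hidden):
            raise ValueError("hidden must be two positive layer widths")
        if self.hidden[0] != self.hidden[1]:
            raise ValueError(
                "tied input/output weights require equal hidden widths"
            )
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lambda_swr < 0:
            raise ValueError("lambda_swr must be >= 0")
        if not 0.0 <= self.input_mask_rate < 1.0:
            raise ValueError("input_mask_rate must lie in [0, 1)")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")

    @property
    def n_voxels(self) -> int:
        return self.grid.n_voxels


class DED:
    """The tied-weight dense encoder-decoder with its parameters."""

    def __init__(self, cfg: DEDConfig):
        self.cfg = cfg
        self.dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        N, k = cfg.n_voxels, cfg.hidden[0]
        dt = self.dtype
        self.W_in = Param(rng.normal(0.0, np.sqrt(2.0 / N), size=(N, k)), dt)
        self.b1 = Param(np.zeros(k), dt)
        self.W_h = Param(rng.normal(0.0, np.sqrt(2.0 / k), size=(k, k)), dt)
        self.b2 = Param(np.zeros(k), dt)
        self.b_out = Param(np.zeros(N), dt)
        self.bn1 = BatchNorm(k, dtype=dt)
        self.bn2 = BatchNorm(k, dtype=dt)
        self._cache = None

    @property
    def W_out(self) -> np.ndarray:
        """Output-layer weights; the transpose of W_in by construction."""
        return self.W_in.value.T

    def params(self) -> list[Param]:
        return [self.W_in, self.b1, self.W_h, self.b2, self.b_out,
                *self.bn1.params(), *self.bn2.params()]

    # -- forward / backward on flat batches ---------------------------------

    def forward_flat(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        bn_training: bool | None = None,
    ) -> np.ndarray:
        """(B, N) binary inputs -> (B, N) probabilities.

        ``training`` enables the Bernoulli input mask (needs ``rng``);
        batch-norm statistics follow ``bn_training`` (defaults to
        ``training``).  Inference is deterministic.
        """
        bn_training = training if bn_training is None else bn_training
        x = np.asarray(x, dtype=self.dtype)
        if training and self.cfg.input_mask_rate > 0.0:
            keep = rng.random(x.shape) >= self.cfg.input_mask_rate
            x0 = x * keep
        else:
            x0 = x
        a1 = x0 @ self.W_in.value + self.b1.value
        n1 = self.bn1.forward(a1, bn_training)
        h1 = relu(n1)
        a2 = h1 @ self.W_h.value + self.b2.value
        n2 = self.bn2.forward(a2, bn_training)
        h2 = relu(n2)
        a3 = h2 @ self.W_in.value.T + self.b_out.value
        p = sigmoid(a3)
        self._cache = (x0, n1, h1, n2, h2, p)
        return p

    def backward_flat(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients from dL/dprobabilities."""
        x0, n1, h1, n2, h2, p = self._cache
        da3 = np.asarray(dprob, dtype=self.dtype) * p * (1.0 - p)
        self.b_out.grad += da3.sum(axis=0)
        self.W_in.grad += da3.T @ h2  # output-layer share of the tied matrix
        dh2 = da3 @ self.W_in.value
        dn2 = dh2 * (n2 > 0)
        da2 = self.bn2.backward(dn2)
        self.b2.grad += da2.sum(axis=0)
        self.W_h.grad += h1.T @ da2
        dh1 = da2 @ self.W_h.value.T
        dn1 = dh1 * (n1 > 0)
        da1 = self.bn1.backward(dn1)
        self.b1.grad += da1.sum(axis=0)
        self.W_in.grad += x0.T @ da1  # input-layer share

    # -- volume-level API ----------------------------------------------------

    def predict(self, volume: OccupancyVolume) -> ProbabilityVolume:
        if volume.grid.dims != self.cfg.grid.dims:
            raise ValueError(
                f"input grid {volume.grid.dims} does not match model grid "
                f"{self.cfg.grid.dims}"
            )
        p = self.forward_flat(volume.values.reshape(1, -1), training=False)
        return ProbabilityVolume(grid=self.cfg.grid, values=p.reshape(self.cfg.grid.dims))

    def reconstruct(self, volume: OccupancyVolume, threshold: float = 0.5) -> OccupancyVolume:
        return binarize(self.predict(volume), threshold)

    def swr_penalty(self) -> float:
        return swr_penalty(self.W_in.value, self.cfg.grid.dims, tied_double=True)

    def roughness(self) -> float:
        """Mean squared spatial gradient per weight entry (untied scale)."""
        return swr_penalty(self.W_in.value, self.cfg.grid.dims,
                           tied_double=False) / self.W_in.value.size


@dataclass
class TrainHistory:
    epoch: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    bce: list[float] = field(default_factory=list)
    dice: list[float] = field(default_factory=list)
    swr: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)


def _stack(pairs, grid, dtype=np.float64) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([p.values.ravel() for p, _ in pairs]).astype(dtype)
    Z = np.stack([z.values.ravel() for _, z in pairs]).astype(dtype)
    return X, Z


def train_ded(
    train_set: list[tuple[OccupancyVolume, OccupancyVolume]],
    val_set: list[tuple[OccupancyVolume, OccupancyVolume]] | None,
    cfg: DEDConfig,
    model: DED | None = None,
    verbose: bool = False,
) -> tuple[DED, TrainHistory]:
    """Minibatch Adam training of the DED on (path, target) volume pairs.

    The total objective is ``loss(x, z) + lambda_swr * swr_penalty / (N k)``
    (the smoothing term enters as a per-weight mean, which keeps the
    named lambda values meaningful across grid sizes); per-sample
    boundary masks are precomputed from the targets when boundary
    enhancement is on.  Deterministic per ``cfg.seed``.
    """
    if not train_set:
        raise ValueError("empty training set")
    model = model if model is not None else DED(cfg)
    dt = model.dtype
    X, Z = _stack(train_set, cfg.grid, dt)
    masks = None
    if cfg.use_boundary_mask:
        masks = np.stack([
            boundary_mask(z, cfg.beta_mask, cfg.sigma_mask, cfg.mask_mode)
            .weights.ravel()
            for _, z in train_set
        ]).astype(dt)
    Xv = Zv = None
    if val_set:
        Xv, Zv = _stack(val_set, cfg.grid, dt)

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    hist = TrainHistory()
    n = len(train_set)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss = ep_bce = ep_dice = 0.0
        n_batches = 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb, zb = X[idx], Z[idx]
            mb = masks[idx] if masks is not None else None
            opt.zero_grad()
            p = model.forward_flat(xb, training=True, rng=rng)
            L, dp, bce_v, dice_v = loss_and_grad(
                p, zb, mb, cfg.alpha, cfg.dice_squared
            )
            if not np.isfinite(L):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {s // cfg.batch_size} "
                    f"(samples {idx.tolist()})"
                )
            model.backward_flat(dp)
            if cfg.lambda_swr > 0.0:
                # penalty enters the objective as a per-weight mean so that
                # lambda is comparable across grid sizes and hidden widths
                swr_grad_accumulate(
                    model.W_in.value, cfg.grid.dims, model.W_in.grad,
                    scale=cfg.lambda_swr / model.W_in.value.size,
                )
            opt.step()
            ep_loss += L
            ep_bce += bce_v
            ep_dice += dice_v
            n_batches += 1
        pen = model.swr_penalty()
        hist.epoch.append(epoch)
        hist.loss.append(ep_loss / n_batches)
        hist.bce.append(ep_bce / n_batches)
        hist.dice.append(ep_dice / n_batches)
        hist.swr.append(pen)
        if Xv is not None:
            pv = model.forward_flat(Xv, training=False)
            _, _, _, vd = loss_and_grad(pv, Zv, None, cfg.alpha)
            hist.val_dice.append(vd)
        else:
            hist.val_dice.append(float("nan"))
        if verbose and (epoch % 10 == 0 or epoch == cfg.epochs - 1):
            print(
                f"epoch {epoch:4d}  loss {hist.loss[-1]:.4f}  "
                f"dice {hist.dice[-1]:.4f}  swr {pen:.3e}"
            )
    return model, hist
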