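"""Volumetric convolutional baseline (V-Net style).

Encoder of conv + max-pool stages that halve the volume, a decoder of
learned 2x upsamplings with same-size skip concatenations, batch
normalization and dropout for regularization, and a sigmoid output.
The first and last convolutions use an enlarged receptive field.  Input
volumes whose dimensions are not divisible by 2^stages are symmetrically
zero-padded and the output cropped back (45^3 -> 48^3 for four stages).

Trained with the same BCE/DICE loss mix as the dense encoder-decoder,
with a uniform mask and no weight-smoothing term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, OccupancyVolume, ProbabilityVolume, binarize
from .nn.core import Adam, BatchNorm, Conv3d, Dropout, MaxPool3d, UpConv3d, sigmoid
from .nn.losses import loss_and_grad


@dataclass
class VNetConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    stages: int = 4
    base_filters: int = 16
    edge_kernel: int = 5  # first and last layers: enlarged receptive field
    inner_kernel: int = 3
    dropout: float = 0.1
    alpha: float = 0.4
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stages < 1:
            raise ValueError("stages must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")

    @property
    def padded_dims(self) -> tuple[int, int, int]:
        m = 2**self.stages
        return tuple(-(-d // m) * m for d in self.grid.dims)


class _ConvBlock:
    """conv -> BN -> ReLU -> dropout."""

    def __init__(self, c_in, c_out, kernel, dropout, rng):
        self.conv = Conv3d(c_in, c_out, kernel, rng)
        self.bn = BatchNorm(c_out)
        self.drop = Dropout(dropout)
        self._pre = None

    def params(self):
        return [*self.conv.params(), *self.bn.params()]

    def forward(self, x, training, rng):
        a = self.conv.forward(x)
        n = self.bn.forward(a, training)
        self._pre = n
        h = np.maximum(n, 0.0)
        return self.drop.forward(h, training, rng)

    def backward(self, dout):
        dh = self.drop.backward(dout)
        dn = dh * (self._pre > 0)
        da = self.bn.backward(dn)
        return self.conv.backward(da)


class VNet:
    """Four-stage (by default) encoder/decoder over occupancy volumes."""

    def __init__(self, cfg: VNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = [cfg.base_filters * 2**i for i in range(cfg.stages)]
        self.enc: list[_ConvBlock] = []
        c_in = 1
        for i in range(cfg.stages):
            k = cfg.edge_kernel if i == 0 else cfg.inner_kernel
            self.enc.append(_ConvBlock(c_in, f[i], k, cfg.dropout, rng))
            c_in = f[i]
        self.pool = MaxPool3d()
        c_bot = cfg.base_filters * 2**cfg.stages
        self.bottom = _ConvBlock(c_in, c_bot, cfg.inner_kernel, cfg.dropout, rng)
        self.ups: list[UpConv3d] = []
        self.dec: list[_ConvBlock] = []
        c_in = c_bot
        for i in reversed(range(cfg.stages)):
            self.ups.append(UpConv3d(c_in, f[i], rng))
            self.dec.append(_ConvBlock(2 * f[i], f[i], cfg.inner_kernel,
                                       cfg.dropout, rng))
            c_in = f[i]
        self.final = Conv3d(c_in, 1, cfg.edge_kernel, rng)
        self._pools: list[MaxPool3d] = []

    def params(self):
        ps = []
        for blk in [*self.enc, self.bottom, *self.dec]:
            ps.extend(blk.params())
        for up in self.ups:
            ps.extend(up.params())
        ps.extend(self.final.params())
        return ps

    # -- forward / backward --------------------------------------------------

    def _pad(self, x: np.ndarray) -> np.ndarray:
        dims = self.cfg.grid.dims
        pdims = self.cfg.padded_dims
        pads = [(0, 0), (0, 0)]
        self._crops = []
        for d, pd in zip(dims, pdims):
            lo = (pd - d) // 2
            pads.append((lo, pd - d - lo))
            self._crops.append(slice(lo, lo + d))
        return np.pad(x, pads)

    def forward_volumes(self, x: np.ndarray, training: bool = False,
                        rng: np.random.Generator | None = None) -> np.ndarray:
        """(B, *dims) binary inputs -> (B, *dims) probabilities."""
        h = self._pad(x[:, None].astype(np.float64))
        skips = []
        self._pools = []
        for blk in self.enc:
            h = blk.forward(h, training, rng)
            skips.append(h)
            pool = MaxPool3d()
            h = pool.forward(h)
            self._pools.append(pool)
        h = self.bottom.forward(h, training, rng)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h = blk.forward(h, training, rng)
        logits = self.final.forward(h)
        self._p = sigmoid(logits)
        out = self._p[:, 0][(slice(None), *self._crops)]
        return out

    def backward_volumes(self, dout: np.ndarray) -> None:
        dp = np.zeros_like(self._p)
        dp[:, 0][(slice(None), *self._crops)] = dout
        dlogits = dp * self._p * (1.0 - self._p)
        dh = self.final.backward(dlogits)
        dskips = []
        for up, blk, c_skip in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            d = blk.backward(dh)
            c_up = d.shape[1] - c_skip
            dskips.append(d[:, c_up:])
            dh = up.backward(d[:, :c_up])
        dh = self.bottom.backward(dh)
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self._pools), reversed(dskips)
        ):
            dh = pool.backward(dh)
            dh = dh + dskip
            dh = blk.backward(dh)

    # -- volume-level API ----------------------------------------------------

    def predict(self, volume: OccupancyVolume) -> ProbabilityVolume:
        if volume.grid.dims != self.cfg.grid.dims:
            raise ValueError("input grid does not match model grid")
        p = self.forward_volumes(volume.values[None], training=False)
        return ProbabilityVolume(grid=self.cfg.grid, values=p[0])

    def reconstruct(self, volume: OccupancyVolume, threshold: float = 0.5) -> OccupancyVolume:
        return binarize(self.predict(volume), threshold)


def train_vnet(
    train_set: list[tuple[OccupancyVolume, OccupancyVolume]],
    val_set: list[tuple[OccupancyVolume, OccupancyVolume]] | None,
    cfg: VNetConfig,
    model: VNet | None = None,
    verbose: bool = False,
):
    """Adam training with the uniform-mask BCE/DICE objective."""
    from .ded import TrainHistory  # same history layout

    if not train_set:
        raise ValueError("empty training set")
    model = model if model is not None else VNet(cfg)
    X = np.stack([p.values for p, _ in train_set]).astype(np.float64)
    Z = np.stack([z.values for _, z in train_set]).astype(np.float64)
    n = len(train_set)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    hist = TrainHistory()
    N = int(np.prod(cfg.grid.dims))
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss = ep_bce = ep_dice = 0.0
        nb = 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            opt.zero_grad()
            p = model.forward_volumes(X[idx], training=True, rng=rng)
            L, dp, bce_v, dice_v = loss_and_grad(
                p.reshape(len(idx), N), Z[idx].reshape(len(idx), N), None, cfg.alpha
            )
            if not np.isfinite(L):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}, batch {nb}")
            model.backward_volumes(dp.reshape(p.shape))
            opt.step()
            ep_loss += L
            ep_bce += bce_v
            ep_dice += dice_v
            nb += 1
        hist.epoch.append(epoch)
        hist.loss.append(ep_loss / nb)
        hist.bce.append(ep_bce / nb)
        hist.dice.append(ep_dice / nb)
        hist.swr.append(0.0)
        hist.val_dice.append(float("nan"))
        if verbose and epoch % 10 == 0:
            print(f"epoch {epoch:4d}  loss {hist.loss[-1]:.4f}  dice {hist.dice[-1]:.4f}")
    return model, hist
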