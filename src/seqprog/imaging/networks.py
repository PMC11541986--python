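"""3D segmentation and joint segmentation/prognosis networks.

`UNet3D` is a residual 3D U-Net: a strided-convolution encoder, a
bottleneck, and a transposed-convolution decoder with skip
connections, ending in a sigmoid voxel-probability head.
`UNEXtractor` shares the same encoder/decoder but adds a radiomic
branch: each encoder level is global-average-pooled, the pooled
vectors are concatenated and reduced by a trainable MLP to a small
deep-radiomics (DLR) vector (default width 6, matching the number of
clinical features), from which a linear head predicts the prognostic
target.  Training the two heads jointly lets the segmentation task
spatially guide the prognostic features toward the organ.

Default channel widths are deliberately small so the networks train on
CPU-scale phantoms; widths are configurable for larger studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import autodiff as F
from ..autodiff import Adam, Tensor
from ..survival_core import dice_loss, npll, weighted_bce, BatchClassStats
from ..neural_core import PReLU

__all__ = ["UNetConfig", "UNet3D", "UNEXtractorConfig", "UNEXtractor",
           "train_unet", "train_unextractor"]


# imaging networks run in single precision: phantom-scale training is
# memory-bandwidth-bound and float32 halves it at no cost to the result
_DTYPE = np.float32


class _Conv:
    def __init__(self, c_in, c_out, k, rng, stride=1, pad=None):
        scale = np.sqrt(2.0 / (c_in * k ** 3))
        self.W = Tensor(rng.normal(0.0, scale, (c_out, c_in, k, k, k)).astype(_DTYPE),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=_DTYPE), requires_grad=True)
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad

    def __call__(self, x):
        return F.conv3d(x, self.W, self.b, stride=self.stride, pad=self.pad)

    def parameters(self):
        return [self.W, self.b]


class _ConvT:
    def __init__(self, c_in, c_out, rng, stride=2):
        scale = np.sqrt(2.0 / (c_in * stride ** 3))
        self.W = Tensor(rng.normal(0.0, scale,
                                   (c_in, c_out, stride, stride, stride)).astype(_DTYPE),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=_DTYPE), requires_grad=True)
        self.stride = stride

    def __call__(self, x):
        return F.conv_transpose3d(x, self.W, self.b, stride=self.stride)

    def parameters(self):
        return [self.W, self.b]


class _InstanceNorm:
    """Per-sample, per-channel normalization over the spatial axes.

    Keeps pre-activations in the sigmoid/PReLU working range; without
    it the deep stack saturates and Dice training stalls.
    """

    def __init__(self, channels, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1), dtype=_DTYPE),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1, 1), dtype=_DTYPE),
                           requires_grad=True)
        self.eps = eps

    def __call__(self, x):
        mu = F.tmean(x, axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = F.tmean(xc * xc, axis=(2, 3, 4), keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        return xn * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class _ConvBlock:
    """conv -> instance norm -> PReLU."""

    def __init__(self, c_in, c_out, k, rng, stride=1, pad=None):
        self.conv = _Conv(c_in, c_out, k, rng, stride=stride, pad=pad)
        self.norm = _InstanceNorm(c_out)
        self.act = _PReLU32()

    def __call__(self, x):
        return self.act.forward(self.norm(self.conv(x)))

    def parameters(self):
        return (self.conv.parameters() + self.norm.parameters()
                + self.act.parameters())


class _ResUnit:
    """norm-conv blocks plus identity skip, then activation."""

    def __init__(self, channels, rng):
        self.b1 = _ConvBlock(channels, channels, 3, rng)
        self.c2 = _Conv(channels, channels, 3, rng)
        self.n2 = _InstanceNorm(channels)
        self.a2 = _PReLU32()

    def __call__(self, x):
        return self.a2.forward(self.n2(self.c2(self.b1(x))) + x)

    def parameters(self):
        return (self.b1.parameters() + self.c2.parameters()
                + self.n2.parameters() + self.a2.parameters())


@dataclass(frozen=True)
class UNetConfig:
    channels: tuple = (8, 16, 32)   # per encoder level, shallow to deep
    in_channels: int = 1

    @property
    def depth(self) -> int:
        return len(self.channels) - 1


class UNet3D:
    """Residual 3D U-Net producing a voxel probability map."""

    def __init__(self, config: UNetConfig = UNetConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        self.stem = _ConvBlock(config.in_channels, ch[0], 3, rng)
        self.down, self.enc_res = [], []
        for a, b in zip(ch[:-1], ch[1:]):
            self.down.append(_ConvBlock(a, b, 3, rng, stride=2))
            self.enc_res.append(_ResUnit(b, rng))
        self.up, self.merge = [], []
        for a, b in zip(ch[:0:-1], ch[-2::-1]):
            self.up.append(_ConvT(a, b, rng))
            self.merge.append(_ConvBlock(2 * b, b, 3, rng))
        self.head = _Conv(ch[0], 1, 1, rng, pad=0)

    def _check(self, x):
        for s in x.shape[2:]:
            if s % (2 ** self.config.depth):
                raise ValueError("spatial size must be divisible by "
                                 f"{2 ** self.config.depth}")

    def encode(self, x):
        """Returns the list of per-level feature maps, shallow to deep."""
        h = self.stem(x)
        feats = [h]
        for down, res in zip(self.down, self.enc_res):
            h = res(down(h))
            feats.append(h)
        return feats

    def decode(self, feats):
        h = feats[-1]
        for up, merge, skip in zip(self.up, self.merge, feats[-2::-1]):
            h = up(h)
            h = merge(F.concatenate([h, skip], axis=1))
        return F.sigmoid(self.head(h))

    def forward(self, x) -> Tensor:
        """x: (N, C, D, H, W) -> voxel probabilities (N, D, H, W)."""
        x = astensor5(x, self.config.in_channels)
        self._check(x)
        probs = self.decode(self.encode(x))
        return probs.reshape((probs.shape[0],) + probs.shape[2:])

    def parameters(self):
        params = self.stem.parameters()
        for blk in (*self.down, *self.enc_res, *self.up, *self.merge, self.head):
            params += blk.parameters()
        return params


class _PReLU32(PReLU):
    def __init__(self, init: float = 0.25):
        self.alpha = Tensor(np.asarray(init, dtype=_DTYPE), requires_grad=True)


def astensor5(x, in_channels: int) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_DTYPE))
    if x.ndim == 3:
        x = x.reshape((1, 1) + x.shape)
    elif x.ndim == 4:
        # (N, D, H, W) single-channel batch or (C, D, H, W) single sample
        if x.shape[0] == in_channels and in_channels > 1:
            x = x.reshape((1,) + x.shape)
        else:
            x = x.reshape((x.shape[0], 1) + x.shape[1:])
    return x


@dataclass(frozen=True)
class UNEXtractorConfig:
    channels: tuple = (8, 16, 32)
    in_channels: int = 2            # CT + PET
    tap_levels: tuple = (0, 1, 2)   # encoder levels feeding the radiomic branch
    dlr_width: int = 6
    reducer_hidden: tuple = (16,)

    @property
    def pooled_width(self) -> int:
        return sum(self.channels[i] for i in self.tap_levels)


class UNEXtractor:
    """Joint prostate segmentation + deep-radiomics extraction network."""

    def __init__(self, config: UNEXtractorConfig = UNEXtractorConfig(),
                 seed: int = 0):
        self.config = config
        if any(i >= len(config.channels) for i in config.tap_levels):
            raise ValueError("tap level out of range")
        self.unet = UNet3D(UNetConfig(config.channels, config.in_channels),
                           seed=seed)
        rng = np.random.default_rng(seed + 1)
        dims = [config.pooled_width, *config.reducer_hidden, config.dlr_width]
        self.reducer = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            scale = np.sqrt(2.0 / a)
            self.reducer.append((
                Tensor(rng.normal(0, scale, (a, b)).astype(_DTYPE), requires_grad=True),
                Tensor(np.zeros(b, dtype=_DTYPE), requires_grad=True),
                _PReLU32() if i < len(dims) - 2 else None))
        self.head_W = Tensor(rng.normal(0, 0.5, (config.dlr_width, 1)).astype(_DTYPE),
                             requires_grad=True)
        self.head_b = Tensor(np.zeros(1, dtype=_DTYPE), requires_grad=True)

    def forward(self, x):
        """x: (N, 2, D, H, W) -> (segmentation probs, DLR vector, prognostic q)."""
        x = astensor5(x, self.config.in_channels)
        feats = self.unet.encode(x)
        seg = self.unet.decode(feats)
        seg = seg.reshape((seg.shape[0],) + seg.shape[2:])
        pooled = F.concatenate(
            [F.tmean(feats[i], axis=(2, 3, 4)) for i in self.config.tap_levels],
            axis=1)
        h = pooled
        for W, b, act in self.reducer:
            h = F.matmul(h, W) + b
            if act is not None:
                h = act.forward(h)
        dlr = h
        q = F.matmul(dlr, self.head_W) + self.head_b
        return seg, dlr, q.reshape((q.shape[0],))

    def parameters(self):
        params = self.unet.parameters()
        for W, b, act in self.reducer:
            params += [W, b] + (act.parameters() if act else [])
        return params + [self.head_W, self.head_b]


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train_unet(model: UNet3D, volumes, masks, *, epochs: int = 20,
               lr: float = 3e-2, batch_size: int = 5, seed: int = 0,
               verbose: bool = False):
    """Train with the soft Dice loss; returns the per-epoch loss log."""
    volumes = np.asarray(volumes, dtype=_DTYPE)
    masks = np.asarray(masks, dtype=_DTYPE)
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    log = []
    for epoch in range(epochs):
        losses = []
        for idx in _batches(len(volumes), batch_size, rng):
            opt.zero_grad()
            probs = model.forward(volumes[idx])
            loss = dice_loss(probs, masks[idx])
            loss.backward()
            opt.step()
            losses.append(loss.item())
        log.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch}: dice loss {log[-1]:.4f}")
    return log


def train_unextractor(model: UNEXtractor, volumes, masks, targets, *,
                      kind: str = "classification", lambda_seg: float = 1.0,
                      epochs: int = 20, lr: float = 1e-2, batch_size: int = 5,
                      seed: int = 0, verbose: bool = False):
    """Joint prognostic + segmentation training.

    Total loss is the prognostic loss (weighted BCE for a binary
    target, NPLL for a survival target given ``targets=(events,
    times)``) plus ``lambda_seg`` times the Dice loss; with
    ``lambda_seg=0`` this reduces to a plain CNN prognostic trainer.
    """
    volumes = np.asarray(volumes, dtype=_DTYPE)
    masks = np.asarray(masks, dtype=_DTYPE)
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    if kind == "classification":
        labels = np.asarray(targets, float)
        if labels.min() == labels.max():
            raise ValueError("prognostic labels are single-class")
        stats = BatchClassStats.from_labels(labels)
    else:
        events, times = (np.asarray(t, float) for t in targets)
        if not (events == 1).any():
            raise ValueError("no events in prognostic labels")
    log = []
    for epoch in range(epochs):
        losses = []
        for idx in _batches(len(volumes), batch_size, rng):
            opt.zero_grad()
            seg, _, q = model.forward(volumes[idx])
            if kind == "classification":
                prog = weighted_bce(F.sigmoid(q), labels[idx], stats)
            else:
                ev = events[idx].astype(bool)
                if not ev.any():
                    continue
                prog = npll(q, ev, times[idx])
            loss = prog if lambda_seg == 0 else prog + lambda_seg * dice_loss(seg, masks[idx])
            loss.backward()
            opt.step()
            losses.append(loss.item())
        log.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch}: joint loss {log[-1]:.4f}")
    return log
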