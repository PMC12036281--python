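"""The 2D encoder-decoder segmentation network.

Architecture, following the 2D nnU-Net convention: each encoder stage
opens with a strided 3x3 convolution (the downsampling step) followed by
a stride-1 3x3 convolution, all with LeakyReLU.  The decoder mirrors the
encoder with kernel-equals-stride transposed convolutions, concatenating
the skip feature from the matching encoder stage before two further 3x3
convolutions (with dropout after the first).  A final transposed
convolution restores full resolution and a 1x1 convolution produces the
class logits, whose spatial size always equals the input's.

The default full-size configuration downsamples a 448x512 patch through
six stages to a 480-channel bottleneck.  Six uniform stride-2 stages
would map the 512-wide axis to 8; the default therefore uses per-axis
factors (2,2)x5 + (2,4), giving a 7x4 bottleneck, with
``uniform_strides=True`` available to select the plain (2,2)x6 scheme
(bottleneck 7x8).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod

import numpy as np

from ..errors import ConfigurationError
from .layers import Conv2d, ConvTranspose2d, Dropout, InstanceNorm2d, LeakyReLU, Param

__all__ = ["NetConfig", "UNet2D", "default_net_config", "small_canvas_net_config"]

CHANNEL_CAP = 480


@dataclass(frozen=True)
class NetConfig:
    """Shape and hyperparameters of the segmentation network.

    ``factors`` are per-stage (row, col) downsampling strides; their
    per-axis products must divide the input size exactly.  The channel
    schedule must be nondecreasing and capped at 480.
    """

    in_rows: int = 448
    in_cols: int = 512
    n_classes: int = 13
    channels: tuple[int, ...] = (32, 64, 128, 256, 480, 480)
    factors: tuple[tuple[int, int], ...] = (
        (2, 2), (2, 2), (2, 2), (2, 2), (2, 2), (2, 4),
    )
    kernel: tuple[int, int] = (3, 3)
    leaky_slope: float = 0.01
    dropout_rate: float = 0.1
    channel_cap: int = CHANNEL_CAP

    @property
    def n_stages(self) -> int:
        return len(self.channels)

    @property
    def bottleneck_shape(self) -> tuple[int, int, int]:
        """(channels, rows, cols) at the deepest stage."""
        fr = prod(f[0] for f in self.factors)
        fc = prod(f[1] for f in self.factors)
        return (self.channels[-1], self.in_rows // fr, self.in_cols // fc)

    def validate(self) -> None:
        if len(self.factors) != len(self.channels):
            raise ConfigurationError("factors and channels must have equal length")
        fr = prod(f[0] for f in self.factors)
        fc = prod(f[1] for f in self.factors)
        if self.in_rows % fr or self.in_cols % fc:
            raise ConfigurationError(
                f"input {self.in_rows}x{self.in_cols} not divisible by "
                f"downsampling factors ({fr}, {fc})"
            )
        if any(a > b for a, b in zip(self.channels, self.channels[1:])):
            raise ConfigurationError("channel schedule must be nondecreasing")
        if max(self.channels) > self.channel_cap:
            raise ConfigurationError(
                f"channel schedule exceeds cap {self.channel_cap}"
            )
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")


def default_net_config(uniform_strides: bool = False) -> NetConfig:
    """Full-size configuration (448x512 -> 480-channel bottleneck)."""
    if uniform_strides:
        return NetConfig(factors=((2, 2),) * 6)  # bottleneck 7x8
    return NetConfig()


def small_canvas_net_config(
    in_rows: int = 112,
    in_cols: int = 128,
    n_classes: int = 13,
    channels: tuple[int, ...] = (16, 32, 64, 128),
    factors: tuple[tuple[int, int], ...] = ((2, 2), (2, 2), (2, 2), (2, 4)),
    dropout_rate: float = 0.1,
) -> NetConfig:
    """Reduced configuration for CPU-scale runs; same 7x4 bottleneck shape."""
    return NetConfig(
        in_rows=in_rows,
        in_cols=in_cols,
        n_classes=n_classes,
        channels=channels,
        factors=factors,
        dropout_rate=dropout_rate,
    )


class _ConvPair:
    """Two conv -> instance norm -> LeakyReLU blocks (the first strided),
    with optional dropout between them."""

    def __init__(self, in_c, out_c, stride, cfg: NetConfig, rng, dropout_seed=None):
        self.conv1 = Conv2d(
            in_c, out_c, kernel=cfg.kernel, stride=stride, rng=rng,
            leaky_slope=cfg.leaky_slope,
        )
        self.norm1 = InstanceNorm2d(out_c)
        self.act1 = LeakyReLU(cfg.leaky_slope)
        self.drop = (
            Dropout(cfg.dropout_rate, seed=dropout_seed)
            if dropout_seed is not None and cfg.dropout_rate > 0
            else None
        )
        self.conv2 = Conv2d(
            out_c, out_c, kernel=cfg.kernel, stride=(1, 1), rng=rng,
            leaky_slope=cfg.leaky_slope,
        )
        self.norm2 = InstanceNorm2d(out_c)
        self.act2 = LeakyReLU(cfg.leaky_slope)

    @property
    def params(self) -> list[Param]:
        return (
            self.conv1.params + self.norm1.params
            + self.conv2.params + self.norm2.params
        )

    def forward(self, x, train=False):
        h = self.act1.forward(self.norm1.forward(self.conv1.forward(x, train), train), train)
        if self.drop is not None:
            h = self.drop.forward(h, train)
        return self.act2.forward(self.norm2.forward(self.conv2.forward(h, train), train), train)

    def backward(self, d):
        d = self.conv2.backward(self.norm2.backward(self.act2.backward(d)))
        if self.drop is not None:
            d = self.drop.backward(d)
        return self.conv1.backward(self.norm1.backward(self.act1.backward(d)))


class UNet2D:
    """Encoder-decoder network over ``(B, 1, rows, cols)`` inputs."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.channels
        S = cfg.n_stages

        self.encoder = [
            _ConvPair(1 if i == 0 else ch[i - 1], ch[i], cfg.factors[i], cfg, rng)
            for i in range(S)
        ]
        # decoder transitions j = S-1 .. 1 (level j -> level j-1)
        self.ups = []
        self.dec_blocks = []
        for j in range(S - 1, 0, -1):
            self.ups.append(
                ConvTranspose2d(ch[j], ch[j - 1], cfg.factors[j], rng=rng)
            )
            self.dec_blocks.append(
                _ConvPair(
                    2 * ch[j - 1], ch[j - 1], (1, 1), cfg, rng,
                    dropout_seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
        self.final_up = ConvTranspose2d(ch[0], ch[0], cfg.factors[0], rng=rng)
        self.final_block = _ConvPair(ch[0], ch[0], (1, 1), cfg, rng)
        self.head = Conv2d(
            ch[0], cfg.n_classes, kernel=(1, 1), stride=(1, 1), pad=(0, 0), rng=rng,
            leaky_slope=cfg.leaky_slope,
        )
        self._skip_channels = [ch[j - 1] for j in range(S - 1, 0, -1)]

    @property
    def params(self) -> list[Param]:
        out: list[Param] = []
        for e in self.encoder:
            out += e.params
        for u, b in zip(self.ups, self.dec_blocks):
            out += u.params + b.params
        out += self.final_up.params + self.final_block.params + self.head.params
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p.value[...] = w

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape ``(B, n_classes, rows, cols)``."""
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2:] != (self.cfg.in_rows, self.cfg.in_cols):
            raise ConfigurationError(
                f"input spatial shape {x.shape[2:]} != configured "
                f"({self.cfg.in_rows}, {self.cfg.in_cols})"
            )
        feats = []
        h = x
        for stage in self.encoder:
            h = stage.forward(h, train)
            feats.append(h)
        for k, (up, block) in enumerate(zip(self.ups, self.dec_blocks)):
            j = len(self.encoder) - 1 - k  # level being left
            h = up.forward(h, train)
            h = np.concatenate([feats[j - 1], h], axis=1)
            h = block.forward(h, train)
        h = self.final_up.forward(h, train)
        h = self.final_block.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients for the last training forward."""
        d = self.head.backward(dlogits)
        d = self.final_block.backward(d)
        d = self.final_up.backward(d)
        S = len(self.encoder)
        dfeats = [None] * S
        for k in range(len(self.ups) - 1, -1, -1):
            j = S - 1 - k
            d = self.dec_blocks[k].backward(d)
            c_skip = self._skip_channels[k]
            dskip, dup = d[:, :c_skip], d[:, c_skip:]
            dfeats[j - 1] = dskip if dfeats[j - 1] is None else dfeats[j - 1] + dskip
            d = self.ups[k].backward(dup)
        dfeats[S - 1] = d if dfeats[S - 1] is None else dfeats[S - 1] + d
        for j in range(S - 1, -1, -1):
            g = self.encoder[j].backward(dfeats[j])
            if j > 0:
                dfeats[j - 1] = dfeats[j - 1] + g

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        from .losses import softmax

        return softmax(self.forward(x, train=False), axis=1)

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel argmax; ties break toward the lowest class code."""
        return np.argmax(self.forward(x, train=False), axis=1).astype(np.int16)
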