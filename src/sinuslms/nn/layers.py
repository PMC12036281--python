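"""Layers with explicit forward/backward passes.

All feature maps are ``(batch, channels, rows, cols)`` arrays.  Each
layer caches what its backward pass needs during a training-mode
forward; inference-mode forwards (``train=False``) skip caching so large
full-resolution passes stay memory-light.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv2d", "ConvTranspose2d", "InstanceNorm2d", "LeakyReLU", "Dropout"]


class Param:
    """A trainable tensor with an accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    @property
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """2D convolution with per-axis stride and symmetric zero padding.

    im2col turns the convolution into one matrix multiply; the backward
    pass scatters column gradients back with a small loop over the
    kernel footprint.  He-normal initialization scaled for LeakyReLU.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int] = (3, 3),
        stride: tuple[int, int] = (1, 1),
        pad: tuple[int, int] | None = None,
        rng: np.random.Generator | None = None,
        leaky_slope: float = 0.01,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        kh, kw = kernel
        self.kernel = (kh, kw)
        self.stride = tuple(stride)
        self.pad = pad if pad is not None else (kh // 2, kw // 2)
        fan_in = in_channels * kh * kw
        std = np.sqrt(2.0 / ((1.0 + leaky_slope**2) * fan_in))
        self.W = Param(rng.normal(0.0, std, (out_channels, in_channels, kh, kw)).astype(dtype))
        self.b = Param(np.zeros(out_channels, dtype=dtype))
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.kernel
        ph, pw = self.pad
        sr, sc = self.stride
        return (h + 2 * ph - kh) // sr + 1, (w + 2 * pw - kw) // sc + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        kh, kw = self.kernel
        ph, pw = self.pad
        sr, sc = self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
        Ho, Wo = self.output_shape(H, W)
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sr, ::sc]
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * Ho * Wo, C * kh * kw
        )
        Wmat = self.W.value.reshape(self.out_channels, -1)
        out = col @ Wmat.T + self.b.value
        self._cache = ((B, C, H, W), col) if train else None
        return out.reshape(B, Ho, Wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (B, C, H, W), col = self._cache
        kh, kw = self.kernel
        ph, pw = self.pad
        sr, sc = self.stride
        _, _, Ho, Wo = dout.shape
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.out_channels)
        self.W.grad += (d2.T @ col).reshape(self.W.value.shape)
        self.b.grad += d2.sum(axis=0)
        dcol = (d2 @ self.W.value.reshape(self.out_channels, -1)).reshape(
            B, Ho, Wo, C, kh, kw
        )
        dxp = np.zeros((B, C, H + 2 * ph, W + 2 * pw), dtype=dout.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + sr * Ho : sr, j : j + sc * Wo : sc] += dcol[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        self._cache = None
        if ph or pw:
            return dxp[:, :, ph : H + ph, pw : W + pw]
        return dxp


class ConvTranspose2d(Layer):
    """Transposed convolution with kernel size equal to stride.

    With kernel == stride the output tiles are disjoint, so the operation
    is a single matmul plus a reshape — the standard upsampling block in
    U-Net style decoders.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: tuple[int, int],
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        sr, sc = stride
        self.stride = (sr, sc)
        std = np.sqrt(2.0 / in_channels)
        self.W = Param(rng.normal(0.0, std, (in_channels, out_channels, sr, sc)).astype(dtype))
        self.b = Param(np.zeros(out_channels, dtype=dtype))
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        sr, sc = self.stride
        xm = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, C)
        out = xm @ self.W.value.reshape(C, -1)  # (B*H*W, O*sr*sc)
        out = out.reshape(B, H, W, self.out_channels, sr, sc)
        out = out.transpose(0, 3, 1, 4, 2, 5).reshape(B, self.out_channels, H * sr, W * sc)
        out += self.b.value[None, :, None, None]
        self._cache = ((B, C, H, W), xm) if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (B, C, H, W), xm = self._cache
        sr, sc = self.stride
        O = self.out_channels
        d = dout.reshape(B, O, H, sr, W, sc).transpose(0, 2, 4, 1, 3, 5)
        d2 = np.ascontiguousarray(d).reshape(-1, O * sr * sc)
        self.W.grad += (xm.T @ d2).reshape(self.W.value.shape)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dx = (d2 @ self.W.value.reshape(C, -1).T).reshape(B, H, W, C).transpose(0, 3, 1, 2)
        self._cache = None
        return dx


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over spatial dims.

    The standard normalization in nnU-Net style segmentation blocks
    (conv -> instance norm -> LeakyReLU); keeps deep stacks trainable at
    large learning rates regardless of batch composition.
    """

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.eps = eps
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        out = xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv) if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = dout * self.gamma.value[None, :, None, None]
        m1 = g.mean(axis=(2, 3), keepdims=True)
        m2 = (g * xhat).mean(axis=(2, 3), keepdims=True)
        self._cache = None
        return inv * (g - m1 - xhat * m2)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mask = x >= 0
        out = np.where(mask, x, self.slope * x)
        self._mask = mask if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dout, self.slope * dout)
        self._mask = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, rate: float, seed: int = 0):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(seed)
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx
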