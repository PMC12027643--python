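"""Multi-Granularity Rough Attention (MGRA) bridge.

Rough-set flavoured attention: the max-pooled statistic of a feature acts
as the *upper* importance bound (possible relevance) and the mean-pooled
statistic as the *lower* bound (certain relevance).

Rough channel attention (RCA) pools spatially (GMP / GAP), maps both
descriptors through a shared bottleneck MLP (reduction r, sigmoid gates)
and mixes them with learnable scalars:

    FC* = a1 * sigmoid(W2 relu(W1 gmp)) + b1 * sigmoid(W2 relu(W1 gap))
    FC  = FC* . F

Rough spatial attention (RSA) pools over channels, passes each
single-channel bound map through a shared 7x7 convolution with ReLU (the
printed pipeline has no sigmoid here; ``rsa_sigmoid`` adds one), mixes
with scalars, and reweights pixels.

MGRA runs RCA and RSA in parallel on the bridge feature, summarises both
outputs by global average pooling, and fuses them with softmax weights
from a two-layer head:

    [alpha, beta] = softmax(Ww relu(W1 [gap(FC); gap(FS)])),
    out = alpha * FC + beta * FS

so the fused map always lies elementwise between FC and FS.
"""

from __future__ import annotations

import numpy as np

from ..nn import Conv2d, Linear, Module, Parameter
from ..tensor import Tensor


def _spatial_max(x: Tensor) -> Tensor:
    """Global max pool over H, W -> (B, C)."""
    B, C, H, W = x.shape
    return x.reshape(B, C, H * W).max(axis=2)


class RoughChannelAttention(Module):
    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        if channels // reduction < 1:
            raise ValueError(
                f"reduction {reduction} collapses {channels} channels below 1"
            )
        self.channels = channels
        self.reduction = reduction
        hidden = channels // reduction
        self.w1 = Linear(channels, hidden, rng, bias=False)
        self.w2 = Linear(hidden, channels, rng, bias=False)
        self.alpha = Parameter(np.float32(0.5))
        self.beta = Parameter(np.float32(0.5))

    def _gate(self, desc: Tensor) -> Tensor:
        return self.w2(self.w1(desc).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"RCA expected {self.channels} channels, got {x.shape[1]}")
        B, C = x.shape[0], x.shape[1]
        upper = self._gate(_spatial_max(x))  # GMP bound
        lower = self._gate(x.mean(axis=(2, 3)))  # GAP bound
        gate = self.alpha * upper + self.beta * lower
        return x * gate.reshape(B, C, 1, 1)


class RoughSpatialAttention(Module):
    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        kernel_size: int = 7,
        use_sigmoid: bool = False,
        stride2_up: bool = False,
    ):
        super().__init__()
        self.channels = channels
        self.use_sigmoid = use_sigmoid
        self.stride2_up = stride2_up
        self.conv = Conv2d(1, 1, kernel_size, rng, bias=True)
        self.alpha = Parameter(np.float32(0.5))
        self.beta = Parameter(np.float32(0.5))

    def _bound_map(self, m: Tensor) -> Tensor:
        y = self.conv(m).relu()
        if self.stride2_up:
            _, _, H, W = y.shape
            y = y[:, :, ::2, ::2].bilinear_resize(H, W)
        if self.use_sigmoid:
            y = y.sigmoid()
        return y

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"RSA expected {self.channels} channels, got {x.shape[1]}")
        upper = self._bound_map(x.max(axis=1, keepdims=True))
        lower = self._bound_map(x.mean(axis=1, keepdims=True))
        return x * (self.alpha * upper + self.beta * lower)


class MGRA(Module):
    """Parallel RCA + RSA with learned convex fusion, at the bridge."""

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        reduction: int = 16,
        rsa_sigmoid: bool = False,
        rsa_stride2_up: bool = False,
    ):
        super().__init__()
        self.channels = channels
        self.rca = RoughChannelAttention(channels, rng, reduction)
        self.rsa = RoughSpatialAttention(
            channels, rng, use_sigmoid=rsa_sigmoid, stride2_up=rsa_stride2_up
        )
        hidden = max(2 * channels // 16, 4)
        self.fuse1 = Linear(2 * channels, hidden, rng, bias=False)
        self.fuse2 = Linear(hidden, 2, rng, bias=False)

    def fusion_weights(self, fc: Tensor, fs: Tensor) -> Tensor:
        """Per-sample (alpha_inter, beta_inter); rows sum to 1."""
        gcs = Tensor.concat([fc.mean(axis=(2, 3)), fs.mean(axis=(2, 3))], axis=1)
        return self.fuse2(self.fuse1(gcs).relu()).softmax(axis=1)

    def forward(self, x: Tensor) -> Tensor:
        fc = self.rca(x)
        fs = self.rsa(x)
        ab = self.fusion_weights(fc, fs)  # (B, 2)
        B = x.shape[0]
        alpha = ab[:, 0:1].reshape(B, 1, 1, 1)
        beta = ab[:, 1:2].reshape(B, 1, 1, 1)
        return fc * alpha + fs * beta
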