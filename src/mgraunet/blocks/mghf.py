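"""Multi-Granularity Hybrid Filtering (MGHF).

The block runs three parallel multi-scale square convolutions (3x3, 5x5,
7x7) alongside three decomposed strip-convolution pairs (Kx1 followed by
1xK, K in {9, 15, 21}), sums the branch outputs, fuses them with a
pointwise convolution and adds a 1x1 residual projection:

    MGHF(X) = PWConv( sum_i Conv_{KixKi}(X) + sum_j Conv_{1xKj}(Conv_{Kjx1}(X)) )
              + ResidualConv(X)

The strip pairs approximate large dense kernels at a fraction of the
parameters while emphasising horizontal/vertical boundary structure.  As
written the block is purely linear (no normalisation or activation), which
makes homogeneity and superposition exactly testable; an optional
``with_norm_act`` flag appends BN+ReLU for use inside larger networks.

``square_mode`` selects dense square convolutions (the literal reading,
default for the standalone block) or depthwise ones (used by the full
network, whose parameter budget cannot accommodate dense multi-scale
kernels at its widths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..nn import BatchNorm2d, Conv2d, Module
from ..tensor import Tensor


@dataclass
class MGHFConfig:
    in_channels: int
    out_channels: int
    square_kernels: list[int] = field(default_factory=lambda: [3, 5, 7])
    strip_kernels: list[int] = field(default_factory=lambda: [9, 15, 21])
    include_bias: bool = True
    square_mode: str = "dense"  # "dense" | "depthwise"
    with_norm_act: bool = False

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if not self.square_kernels or not self.strip_kernels:
            raise ValueError("square_kernels and strip_kernels must be nonempty")
        for k in list(self.square_kernels) + list(self.strip_kernels):
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and >= 1, got {k}")
        if self.square_mode not in ("dense", "depthwise"):
            raise ValueError(f"unknown square_mode {self.square_mode!r}")
        if self.square_mode == "depthwise" and self.in_channels != self.out_channels:
            raise ValueError("depthwise square branches require in_channels == out_channels")


class MGHF(Module):
    def __init__(self, cfg: MGHFConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        cin, cout, b = cfg.in_channels, cfg.out_channels, cfg.include_bias
        groups = cout if cfg.square_mode == "depthwise" else 1
        self.squares = [
            Conv2d(cin, cout, k, rng, groups=groups, bias=b) for k in cfg.square_kernels
        ]
        # Kx1 stage carries the channel projection, 1xK stage is depth-preserving
        self.strips_v = [Conv2d(cin, cout, (k, 1), rng, bias=b) for k in cfg.strip_kernels]
        self.strips_h = [Conv2d(cout, cout, (1, k), rng, bias=b) for k in cfg.strip_kernels]
        self.pointwise = Conv2d(cout, cout, 1, rng, bias=b)
        self.residual = Conv2d(cin, cout, 1, rng, bias=b)
        self.bn = BatchNorm2d(cout) if cfg.with_norm_act else None
        # branch-sum aware init: keep the summed-branch variance comparable
        # to a single branch so deep stacks stay well conditioned
        scale = 1.0 / np.sqrt(len(self.squares) + len(self.strips_v))
        for conv in self.squares + self.strips_v:
            conv.weight.data *= scale

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"MGHF expected {self.cfg.in_channels} input channels, got {x.shape[1]}"
            )
        acc = self.squares[0](x)
        for conv in self.squares[1:]:
            acc = acc + conv(x)
        for cv, ch in zip(self.strips_v, self.strips_h):
            acc = acc + ch(cv(x))
        out = self.pointwise(acc) + self.residual(x)
        if self.bn is not None:
            out = self.bn(out).relu()
        return out


def mghf_param_count(cfg: MGHFConfig) -> int:
    """Closed-form trainable-parameter count of :class:`MGHF`."""
    cin, cout = cfg.in_channels, cfg.out_channels
    b = 1 if cfg.include_bias else 0
    total = 0
    for k in cfg.square_kernels:
        if cfg.square_mode == "dense":
            total += k * k * cin * cout + b * cout
        else:
            total += k * k * cout + b * cout
    for k in cfg.strip_kernels:
        total += k * cin * cout + b * cout  # Kx1 projection stage
        total += k * cout * cout + b * cout  # 1xK depth-preserving stage
    total += cout * cout + b * cout  # pointwise fusion
    total += cin * cout + b * cout  # residual projection
    if cfg.with_norm_act:
        total += 2 * cout
    return total
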