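"""Neural-network layers on top of the autograd :class:`~mgraunet.tensor.Tensor`.

Layers mirror the conventional convolutional toolbox: ``Conv2d`` (stride 1,
"same" zero padding, optional channel groups for depthwise filters),
``BatchNorm2d`` with running statistics, ``Linear``, 2x2 max pooling and
bilinear upsampling.  Construction is deterministic given the NumPy
``Generator`` passed to each layer.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: parameter discovery, train/eval, state dict."""

    def __init__(self):
        self.training = True
        self._last_io: tuple | None = None  # (input shape, output shape) trace

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, *args, **kwargs):
        out = self.forward(x, *args, **kwargs)
        if isinstance(x, Tensor) and isinstance(out, Tensor):
            self._last_io = (x.shape, out.shape)
        return out

    # -- traversal -----------------------------------------------------
    def children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for c in self.children():
            yield from c.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Parameter):
                        yield f"{name}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        for name, m in self._named_modules():
            for bk, bv in getattr(m, "_buffers", {}).items():
                state[f"{name}{bk}"] = bv.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        buffers = {
            f"{name}{bk}": (m, bk)
            for name, m in self._named_modules()
            for bk in getattr(m, "_buffers", {})
        }
        for k, v in state.items():
            if k in own:
                if own[k].shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}: {own[k].shape} vs {v.shape}")
                own[k].data = np.asarray(v, dtype=np.float32)
            elif k in buffers:
                m, bk = buffers[k]
                m._buffers[bk] = np.asarray(v, dtype=np.float32)
            else:
                raise KeyError(f"unexpected key in state dict: {k}")
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{k}.{i}.")


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """Stride-1 'same'-padded convolution; ``groups=in_channels`` is depthwise."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        rng: np.random.Generator,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.groups = (kh, kw), groups
        fan_in = (in_channels // groups) * kh * kw
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels // groups, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        return x.conv2d(self.weight, self.bias, groups=self.groups)

    def macs(self, out_shape) -> int:
        _, _, ho, wo = out_shape
        kh, kw = self.kernel_size
        return kh * kw * (self.in_channels // self.groups) * self.out_channels * ho * wo


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out

    def macs(self, out_shape) -> int:
        batch = int(np.prod(out_shape[:-1]))
        return batch * self.in_features * self.out_features


class BatchNorm2d(Module):
    """Per-channel normalization; batch statistics in training, running in eval.

    ``freeze_stats()`` pins the layer to its running statistics regardless of
    mode, which keeps unit tests deterministic.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features, self.eps, self.momentum = num_features, eps, momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self._buffers = {
            "running_mean": np.zeros(num_features, dtype=np.float32),
            "running_var": np.ones(num_features, dtype=np.float32),
        }
        self.frozen = False

    def freeze_stats(self):
        self.frozen = True
        return self

    def forward(self, x: Tensor) -> Tensor:
        if self.training and not self.frozen:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(-1)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(-1)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, -1, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, -1, 1, 1))
        xn = (x - mu) / ((var + self.eps) ** 0.5)
        w = self.weight.reshape(1, self.num_features, 1, 1)
        b = self.bias.reshape(1, self.num_features, 1, 1)
        return xn * w + b


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2x2()


class BilinearUpsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        return x.bilinear_resize(h * 2, w * 2)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.weight = Parameter(_kaiming(rng, (in_channels, out_channels, 2, 2), in_channels * 4))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2x2(self.weight, self.bias)

    def macs(self, out_shape) -> int:
        _, _, ho, wo = out_shape
        return self.in_channels * self.out_channels * ho * wo


class ConvBNReLU(Module):
    """3x3 convolution -> batch norm -> ReLU, the plain stage block."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel_size: int = 3):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel_size, rng, bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class SeparableConvBNReLU(Module):
    """Depthwise 3x3 + pointwise 1x1 -> BN -> ReLU (lightweight stage block)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.depthwise = Conv2d(cin, cin, 3, rng, groups=cin, bias=False)
        self.pointwise = Conv2d(cin, cout, 1, rng, bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.pointwise(self.depthwise(x))).relu()


class AdamW:
    """Decoupled weight-decay Adam (Loshchilov & Hutter)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-2):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class CosineAnnealingLR:
    """Half-cosine decay from the initial rate to ``eta_min`` over ``t_max`` steps."""

    def __init__(self, optimizer: AdamW, t_max: int, eta_min: float = 0.0):
        self.optimizer = optimizer
        self.t_max, self.eta_min = t_max, eta_min
        self.base_lr = optimizer.lr
        self.epoch = 0

    def step(self):
        self.epoch += 1
        frac = min(self.epoch, self.t_max) / self.t_max
        self.optimizer.lr = self.eta_min + 0.5 * (self.base_lr - self.eta_min) * (
            1 + np.cos(np.pi * frac)
        )
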