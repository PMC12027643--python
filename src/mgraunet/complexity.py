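"""Parameter and FLOP accounting.

Counting convention: one multiply-accumulate (MAC) is reported as one
FLOP; only convolution, transposed-convolution and fully connected
layers are counted, normalisation / activation / pooling / resampling
are excluded.  This is the convention commonly used when reporting
lightweight segmentation networks.  The FLOP count is obtained by
tracing a forward pass at the declared input size, so every layer is
counted at the spatial resolution it actually sees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, ConvTranspose2x2, Linear, Module
from .tensor import Tensor, no_grad

logger = logging.getLogger(__name__)

CONVENTION = (
    "1 MAC = 1 FLOP; conv/transposed-conv/linear layers only; "
    "BN, activations, pooling and resampling excluded"
)

_COUNTED = (Conv2d, ConvTranspose2x2, Linear)
_UNCOUNTED_OK = (BatchNorm2d,)  # parameterised layers deliberately excluded


@dataclass
class ComplexityReport:
    param_count: int
    flops: float
    input_size: tuple[int, int, int]
    convention: str = CONVENTION

    @property
    def params_m(self) -> float:
        return self.param_count / 1e6

    @property
    def flops_g(self) -> float:
        return self.flops / 1e9

    def __str__(self) -> str:
        c, h, w = self.input_size
        return (
            f"Params: {self.params_m:.2f} M | FLOPs: {self.flops_g:.2f} G "
            f"at {c}x{h}x{w} [{self.convention}]"
        )


def count_parameters(model: Module) -> int:
    """Total size of all trainable weight containers."""
    return model.num_parameters()


def count_flops(model: Module, input_size: tuple[int, int, int] = (3, 256, 256)) -> float:
    """MACs of one forward pass at ``input_size``, per the declared convention."""
    model.eval()
    c, h, w = input_size
    with no_grad():
        model(Tensor(np.zeros((1, c, h, w), dtype=np.float32)))
    total = 0
    for m in model.modules():
        if isinstance(m, _COUNTED):
            if m._last_io is None:
                logger.warning("layer %s never saw input during trace; counted as 0", m)
                continue
            total += m.macs(m._last_io[1])
        elif list(m.children()) == [] and not isinstance(m, _UNCOUNTED_OK):
            if any(True for _ in m.named_parameters()):
                pnames = [n for n, _ in m.named_parameters()]
                if any("." not in n for n in pnames):
                    logger.warning(
                        "unsupported parameterised layer %s counted as 0 FLOPs",
                        type(m).__name__,
                    )
    return float(total)


def complexity_report(
    model: Module, input_size: tuple[int, int, int] = (3, 256, 256)
) -> ComplexityReport:
    return ComplexityReport(
        param_count=count_parameters(model),
        flops=count_flops(model, input_size),
        input_size=tuple(input_size),
    )
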