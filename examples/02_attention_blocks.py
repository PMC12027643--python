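"""The three attention/filtering blocks on a toy feature map.

Runs multi-granularity hybrid filtering (MGHF), dynamic granular
partition synergy (DGPS) and rough attention fusion (MGRA) on a small
random feature map and prints the quantities that characterise each:
MGHF's shape-preserving multi-branch output, DGPS's adaptive partition
count and row-stochastic synergy weights, and MGRA's convex channel/
spatial fusion weights (which always sum to 1).
"""

import numpy as np

from mgraunet import (
    MGHF,
    MGHFConfig,
    MGRA,
    DGPS,
    partition,
    similarity_matrix,
    synergy_weights,
)
from mgraunet.tensor import Tensor

rng = np.random.default_rng(0)
x = rng.normal(size=(1, 8, 16, 16)).astype(np.float32)

mghf = MGHF(MGHFConfig(8, 8), rng)
y = mghf(Tensor(x))
print(f"MGHF: {x.shape} -> {y.shape}  (3 square + 3 strip-pair branches + residual)")

p = partition(x[0])
S = similarity_matrix(p)
A = synergy_weights(S)
print(f"DGPS partition: n={p.n} regions (variance-adaptive quadtree)")
print(f"  synergy row sums: {A.sum(axis=1).round(6)}  (softmax over cosine similarity)")
dgps = DGPS(8, rng)
print(f"  block output shape: {dgps(Tensor(x)).shape}")

mgra = MGRA(8, rng, reduction=2)
fc, fs = mgra.rca(Tensor(x)), mgra.rsa(Tensor(x))
ab = mgra.fusion_weights(fc, fs).data[0]
print(f"MGRA fusion weights (alpha, beta) = ({ab[0]:.4f}, {ab[1]:.4f}), sum = {ab.sum():.6f}")
print("  output lies elementwise between the channel- and spatial-attention branches")
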