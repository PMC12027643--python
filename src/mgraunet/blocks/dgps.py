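"""Dynamic Granular Partition Synergy attention (DGPS).

The block tiles a feature map into content-adaptive regions, measures
inter-region affinity by cosine similarity of channel-mean descriptors,
exchanges information between regions through softmax "synergy" weights,
reassembles the refined regions and applies a 1x1 convolution with batch
norm and a residual ReLU fusion:

    O = ReLU( BN(Conv_1x1(assemble({F'_1..F'_n}))) + X ),
    F'_i = sum_j a_ij * resize(F_j -> shape_i),
    a_ij = softmax_j(cos(d_i, d_j))

The partition policy is a one-level quadtree: start from a 2x2 grid and
subdivide any region whose value variance exceeds the mean variance of
the current regions, down to a minimum region side and a cap on the
region count.  A fixed uniform grid policy is available for ablation.

The module functions here (:func:`partition`, :func:`similarity_matrix`,
:func:`synergy_weights`, :func:`aggregate`, :func:`assemble`) operate on
plain NumPy arrays and define the reference semantics; :class:`DGPS`
re-expresses the same computation on autograd tensors so the network can
train through it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..nn import BatchNorm2d, Conv2d, Module
from ..tensor import Tensor, _interp_matrix

logger = logging.getLogger(__name__)


@dataclass
class PartitionStrategy:
    policy: str = "quadtree"  # "quadtree" | "grid"
    grid: tuple[int, int] = (2, 2)
    min_region: int = 2
    max_regions: int = 16

    def __post_init__(self):
        if self.policy not in ("quadtree", "grid"):
            raise ValueError(f"unknown partition policy {self.policy!r}")
        if self.min_region < 1 or self.max_regions < 1:
            raise ValueError("min_region and max_regions must be positive")


@dataclass
class PartitionSet:
    """Ordered tiling of a (C, H, W) map with channel-mean descriptors."""

    placements: list[tuple[int, int, int, int]]  # (top, left, height, width)
    regions: list[np.ndarray]  # each (C, Hi, Wi)
    descriptors: np.ndarray  # (n, C)
    source_shape: tuple[int, int, int]

    @property
    def n(self) -> int:
        return len(self.placements)


def _grid_placements(H: int, W: int, gh: int, gw: int):
    hs = [H // gh + (1 if i < H % gh else 0) for i in range(gh)]
    ws = [W // gw + (1 if j < W % gw else 0) for j in range(gw)]
    tops = np.concatenate([[0], np.cumsum(hs)[:-1]])
    lefts = np.concatenate([[0], np.cumsum(ws)[:-1]])
    return [
        (int(tops[i]), int(lefts[j]), hs[i], ws[j])
        for i in range(gh)
        for j in range(gw)
    ]


def _quarter(placement):
    t, l, h, w = placement
    h1, w1 = h // 2, w // 2
    return [
        (t, l, h1, w1),
        (t, l + w1, h1, w - w1),
        (t + h1, l, h - h1, w1),
        (t + h1, l + w1, h - h1, w - w1),
    ]


def partition(f: np.ndarray, strategy: PartitionStrategy | None = None) -> PartitionSet:
    """Tile a (C, H, W) feature map into regions per the chosen policy.

    Maps too small to honour the minimum region size fall back to a single
    region covering the whole map (with a logged notice).
    """
    strategy = strategy or PartitionStrategy()
    f = np.asarray(f)
    if f.ndim != 3:
        raise ValueError(f"expected a (C, H, W) map, got shape {f.shape}")
    C, H, W = f.shape

    if strategy.policy == "grid":
        gh, gw = strategy.grid
        if H < gh or W < gw:
            logger.info("map %dx%d smaller than grid %dx%d; falling back to n=1", H, W, gh, gw)
            placements = [(0, 0, H, W)]
        else:
            placements = _grid_placements(H, W, gh, gw)
    else:  # quadtree
        if H < 2 * strategy.min_region or W < 2 * strategy.min_region:
            logger.info("map %dx%d below minimum split size; falling back to n=1", H, W)
            placements = [(0, 0, H, W)]
        else:
            base = _grid_placements(H, W, 2, 2)
            scores = [float(f[:, t : t + h, l : l + w].var()) for t, l, h, w in base]
            mean_score = float(np.mean(scores))
            placements = []
            budget = strategy.max_regions - len(base)
            for p, s in zip(base, scores):
                _, _, h, w = p
                splittable = h // 2 >= strategy.min_region and w // 2 >= strategy.min_region
                if s > mean_score and splittable and budget >= 3:
                    placements.extend(_quarter(p))
                    budget -= 3
                else:
                    placements.append(p)

    regions = [f[:, t : t + h, l : l + w] for t, l, h, w in placements]
    descriptors = np.stack([r.mean(axis=(1, 2)) for r in regions])
    return PartitionSet(placements, regions, descriptors, (C, H, W))


def similarity_matrix(p: PartitionSet) -> np.ndarray:
    """Cosine similarity between region descriptors; symmetric, unit diagonal.

    Zero-norm descriptors get similarity 0 with every other region and 1
    with themselves rather than raising a division error.
    """
    D = p.descriptors.astype(np.float64)
    norms = np.linalg.norm(D, axis=1)
    zero = norms == 0
    if zero.any():
        logger.info("%d zero-norm descriptors in similarity computation", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    S = (D @ D.T) / np.outer(safe, safe)
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.fill_diagonal(S, 1.0)
    return np.clip(S, -1.0, 1.0)


def synergy_weights(s: np.ndarray) -> np.ndarray:
    """Row-wise softmax of the similarity matrix."""
    s = np.asarray(s, dtype=np.float64)
    if not np.isfinite(s).all():
        raise ValueError("similarity matrix contains non-finite entries")
    e = np.exp(s - s.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _resize_chw(r: np.ndarray, h: int, w: int) -> np.ndarray:
    if r.shape[1:] == (h, w):
        return r
    Rh = _interp_matrix(r.shape[1], h)
    Rw = _interp_matrix(r.shape[2], w)
    return np.einsum("oi,cij,pj->cop", Rh, r, Rw, optimize=True)


def aggregate(p: PartitionSet, a: np.ndarray) -> PartitionSet:
    """Refine each region as the synergy-weighted sum of all regions."""
    a = np.asarray(a)
    if a.shape != (p.n, p.n):
        raise ValueError(f"weights shape {a.shape} does not match n={p.n}")
    refined = []
    for i, (t, l, h, w) in enumerate(p.placements):
        acc = np.zeros((p.source_shape[0], h, w))
        for j, r in enumerate(p.regions):
            acc += a[i, j] * _resize_chw(r, h, w)
        refined.append(acc)
    descriptors = np.stack([r.mean(axis=(1, 2)) for r in refined])
    return PartitionSet(list(p.placements), refined, descriptors, p.source_shape)


def assemble(p: PartitionSet) -> np.ndarray:
    """Paste regions back into a full (C, H, W) map by their placements."""
    C, H, W = p.source_shape
    out = np.zeros((C, H, W), dtype=p.regions[0].dtype)
    for (t, l, h, w), r in zip(p.placements, p.regions):
        out[:, t : t + h, l : l + w] = r
    return out


class DGPS(Module):
    """Autograd DGPS block; numerically matches the functional composition."""

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        strategy: PartitionStrategy | None = None,
    ):
        super().__init__()
        self.channels = channels
        self.strategy = strategy or PartitionStrategy()
        self.conv = Conv2d(channels, channels, 1, rng, bias=False)
        self.bn = BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"DGPS expected {self.channels} channels, got {x.shape[1]}")
        B = x.shape[0]
        refined = [self._refine_sample(x[b : b + 1]) for b in range(B)]
        assembled = refined[0] if B == 1 else Tensor.concat(refined, axis=0)
        return (self.bn(self.conv(assembled)) + x).relu()

    def _refine_sample(self, xs: Tensor) -> Tensor:
        _, C, H, W = xs.shape
        placements = partition(xs.data[0], self.strategy).placements
        n = len(placements)
        if n == 1:
            return xs
        regions = [xs[:, :, t : t + h, l : l + w] for t, l, h, w in placements]
        descs = Tensor.concat([r.mean(axis=(2, 3)) for r in regions], axis=0)  # (n, C)
        normsq = (descs * descs).sum(axis=1, keepdims=True)
        norm = (normsq + 1e-12).sqrt()
        S = (descs @ descs.transpose(1, 0)) / (norm @ norm.transpose(1, 0))
        eye = np.eye(n, dtype=np.float32)
        S = S * (1.0 - eye) + Tensor(eye)  # exact unit self-similarity
        A = S.softmax(axis=1)

        # group receivers by shape so the weighted sum is a single matmul
        out = [None] * n
        shapes = sorted({(h, w) for _, _, h, w in placements})
        for h, w in shapes:
            rows = [i for i, (_, _, hi, wi) in enumerate(placements) if (hi, wi) == (h, w)]
            stack = Tensor.concat(
                [r.bilinear_resize(h, w).reshape(1, C * h * w) for r in regions], axis=0
            )  # (n, C*h*w)
            mixed = A[rows] @ stack  # (len(rows), C*h*w)
            for k, i in enumerate(rows):
                out[i] = mixed[k : k + 1].reshape(1, C, h, w)

        placed = [
            r.pad2d_asym(t, H - t - h, l, W - l - w)
            for r, (t, l, h, w) in zip(out, placements)
        ]
        total = placed[0]
        for p in placed[1:]:
            total = total + p
        return total
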