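"""Brute-force reference implementations used across the test suite."""

import numpy as np


def naive_conv2d(x, w, b=None, groups=1):
    """Nested-loop stride-1 'same' cross-correlation oracle.

    x: (B, Cin, H, W); w: (Cout, Cin/groups, kh, kw); zero padding.
    """
    B, cin, H, W = x.shape
    cout, cin_g, kh, kw = w.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x.astype(np.float64), ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((B, cout, H, W))
    co_g = cout // groups
    for bi in range(B):
        for o in range(cout):
            g = o // co_g
            for i in range(H):
                for j in range(W):
                    acc = 0.0
                    for c in range(cin_g):
                        for u in range(kh):
                            for v in range(kw):
                                acc += (
                                    w[o, c, u, v]
                                    * xp[bi, g * cin_g + c, i + u, j + v]
                                )
                    out[bi, o, i, j] = acc
            if b is not None:
                out[bi, o] += b[o]
    return out


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def mghf_oracle(x, block, conv_oracle=naive_conv2d):
    """Term-by-term evaluation of the filtering block with the nested-loop
    convolution."""
    acc = np.zeros((x.shape[0], block.cfg.out_channels, x.shape[2], x.shape[3]))
    groups = block.cfg.out_channels if block.cfg.square_mode == "depthwise" else 1
    for conv in block.squares:
        acc += conv_oracle(x, conv.weight.data, conv.bias.data if conv.bias else None, groups)
    for cv, ch in zip(block.strips_v, block.strips_h):
        mid = conv_oracle(x, cv.weight.data, cv.bias.data if cv.bias else None)
        acc += conv_oracle(mid, ch.weight.data, ch.bias.data if ch.bias else None)
    pw = block.pointwise
    res = block.residual
    out = conv_oracle(acc, pw.weight.data, pw.bias.data if pw.bias else None)
    return out + conv_oracle(x, res.weight.data, res.bias.data if res.bias else None)


def rca_oracle(x, blk):
    """Scalar straight-line evaluation of the channel-attention equations."""
    B, C = x.shape[:2]
    upper_desc = x.max(axis=(2, 3))
    lower_desc = x.mean(axis=(2, 3))
    w1, w2 = blk.w1.weight.data, blk.w2.weight.data
    gate = lambda d: sigmoid(np.maximum(d @ w1, 0.0) @ w2)
    fc_star = blk.alpha.item() * gate(upper_desc) + blk.beta.item() * gate(lower_desc)
    return x * fc_star.reshape(B, C, 1, 1)


def rsa_oracle(x, blk, conv_oracle=naive_conv2d):
    upper = x.max(axis=1, keepdims=True)
    lower = x.mean(axis=1, keepdims=True)
    w, b = blk.conv.weight.data, blk.conv.bias.data
    bound = lambda m: np.maximum(conv_oracle(m, w, b), 0.0)
    return x * (blk.alpha.item() * bound(upper) + blk.beta.item() * bound(lower))


def mgra_oracle(x, blk, conv_oracle=naive_conv2d):
    fc = rca_oracle(x, blk.rca)
    fs = rsa_oracle(x, blk.rsa, conv_oracle)
    gcs = np.concatenate([fc.mean(axis=(2, 3)), fs.mean(axis=(2, 3))], axis=1)
    z = np.maximum(gcs @ blk.fuse1.weight.data, 0.0) @ blk.fuse2.weight.data
    e = np.exp(z - z.max(axis=1, keepdims=True))
    ab = e / e.sum(axis=1, keepdims=True)
    return ab[:, 0].reshape(-1, 1, 1, 1) * fc + ab[:, 1].reshape(-1, 1, 1, 1) * fs
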