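"""Convolution, pooling and loss primitives with hand-written backward passes.

Convolutions are stride-1 (the networks downsample only through pooling and
upsample through 2x2 stride-2 transposed convolution), implemented as im2col +
matmul, which is the fastest pure-NumPy route at these sizes.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2d_2x2",
    "max_pool2d",
    "global_avg_pool",
    "cross_entropy_logits",
    "softmax",
]


def _im2col(xp: np.ndarray, k: int, dilation: int, ho: int, wo: int) -> np.ndarray:
    """View of the padded input as (N, C, k, k, ho, wo), stride 1."""
    n, c, _, _ = xp.shape
    s0, s1, s2, s3 = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, c, k, k, ho, wo), (s0, s1, s2 * dilation, s3 * dilation, s2, s3)
    )


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, stride 1.

    x: (N, C, H, W); weight: (O, C, k, k); bias: (O,) or None.
    """
    n, c, h, w = x.shape
    o, c_w, k, k2 = weight.shape
    if c_w != c or k != k2:
        raise ValueError(f"weight shape {weight.shape} incompatible with input {x.shape}")
    span = dilation * (k - 1) + 1
    ho, wo = h + 2 * padding - span + 1, w + 2 * padding - span + 1
    if ho <= 0 or wo <= 0:
        raise ValueError("convolution output would be empty")

    def make_cols():
        if padding:
            xp = np.pad(x.data,
                        ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        else:
            xp = x.data
        cols = np.ascontiguousarray(_im2col(xp, k, dilation, ho, wo))
        return cols.reshape(n, c * k * k, ho * wo)

    w_m = weight.data.reshape(o, c * k * k)
    out = np.matmul(w_m, make_cols()).reshape(n, o, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        # im2col is recomputed here (x.data is alive anyway) instead of cached:
        # caching would hold k*k times the activation memory across the graph.
        g_m = g.reshape(n, o, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            cols_m = make_cols()
            dw = np.matmul(g_m, cols_m.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dw.reshape(o, c, k, k))
        if x.requires_grad:
            dcols = np.matmul(w_m.T, g_m).reshape(n, c, k, k, ho, wo)
            dxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=g.dtype)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki * dilation:ki * dilation + ho,
                        kj * dilation:kj * dilation + wo] += dcols[:, :, ki, kj]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor._result(out, parents, backward)


def conv_transpose2d_2x2(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (non-overlapping upsampling).

    x: (N, C, H, W); weight: (C, O, 2, 2) -> output (N, O, 2H, 2W).
    """
    n, c, h, w = x.shape
    c_w, o, k, _ = weight.shape
    if c_w != c or k != 2:
        raise ValueError(f"weight shape {weight.shape} incompatible with input {x.shape}")
    # out[n,o,2i+ki,2j+kj] = sum_c x[n,c,i,j] * w[c,o,ki,kj]
    y = np.einsum("ncij,cokl->noikjl", x.data, weight.data, optimize=True)
    out = y.reshape(n, o, 2 * h, 2 * w)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g6 = g.reshape(n, o, h, 2, w, 2)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.einsum("noikjl,ncij->cokl", g6, x.data, optimize=True)
            weight._accumulate(dw)
        if x.requires_grad:
            dx = np.einsum("noikjl,cokl->ncij", g6, weight.data, optimize=True)
            x._accumulate(dx)

    return Tensor._result(out, parents, backward)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; trailing odd row/column dropped."""
    n, c, h, w = x.shape
    ho, wo = h // 2, w // 2
    xc = x.data[:, :, : ho * 2, : wo * 2]
    windows = xc.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, ho, wo, 4)
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dwin = np.zeros_like(windows)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dxc = dwin.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho * 2, wo * 2)
        if (h, w) == (ho * 2, wo * 2):
            x._accumulate(dxc)
        else:
            dx = np.zeros_like(x.data)
            dx[:, :, : ho * 2, : wo * 2] = dxc
            x._accumulate(dx)

    return Tensor._result(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Adaptive average pooling to 1x1, flattened: (N,C,H,W) -> (N,C)."""
    return x.mean(axis=(2, 3))


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax along `axis` (shift is treated as constant)."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy. logits: (M, K); labels: (M,) ints in [0,K)."""
    labels = np.asarray(labels)
    m, k = logits.shape
    if labels.shape != (m,):
        raise ValueError(f"labels shape {labels.shape} does not match logits {logits.shape}")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(m), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(m), labels] -= 1.0
        logits._accumulate((g / m) * p)

    return Tensor._result(np.asarray(loss, dtype=logits.dtype), (logits,), backward)
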