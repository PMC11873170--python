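"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (nested loops, direct formulas) and
written without reference to the package internals, so agreement is evidence
of correctness rather than of shared bugs.
"""

import numpy as np
import pytest

from ifrcnet.data_pipeline import standardize
from ifrcnet.synthetic_data import SceneParams, make_dataset


# --------------------------------------------------------------------- oracles
def naive_conv2d(x, w, b=None, padding=0, dilation=1):
    """Nested-loop 2-D cross-correlation, stride 1. x: (N,C,H,W); w: (O,C,k,k)."""
    n, c, h, wd = x.shape
    o, _, k, _ = w.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    span = dilation * (k - 1) + 1
    ho, wo = h + 2 * padding - span + 1, wd + 2 * padding - span + 1
    out = np.zeros((n, o, ho, wo))
    for ni in range(n):
        for oi in range(o):
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for ci in range(c):
                        for ki in range(k):
                            for kj in range(k):
                                acc += (x[ni, ci, i + ki * dilation, j + kj * dilation]
                                        * w[oi, ci, ki, kj])
                    out[ni, oi, i, j] = acc
            if b is not None:
                out[ni, oi] += b[oi]
    return out


def naive_boundary(mask):
    """Foreground pixels with at least one 4-neighbour outside the foreground."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    pts = []
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    pts.append((i, j))
                    break
    return np.array(pts, dtype=float).reshape(-1, 2)


def naive_hausdorff(a, b):
    """Symmetric Hausdorff distance by explicit double maximin."""
    def directed(p, q):
        return max(min(float(np.hypot(*(pi - qi))) for qi in q) for pi in p)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return max(directed(a, b), directed(b, a))


def naive_seg_metrics(pred, truth):
    """MIoU over {background, foreground}, Dice, boundary Hausdorff."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    miou = 0.5 * (tp / (fn + tp + fp) + tn / (fp + tn + fn))
    dice = 2 * tp / (fn + 2 * tp + fp)
    hd = naive_hausdorff(naive_boundary(pred), naive_boundary(truth))
    return miou, dice, hd


def numeric_grad(f, x, eps=1e-4):
    """Central-difference gradient of scalar f with respect to array x."""
    x = x.astype(np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = f(x)
        x[idx] = orig - eps
        lo = f(x)
        x[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


def random_blob_mask(rng, size):
    """A nonempty blob-like binary mask: a random filled ellipse plus noise bits."""
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    r0, c0 = rng.uniform(1, size - 2, 2)
    a, b = rng.uniform(1.0, size / 2, 2)
    mask = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
    mask |= rng.random((size, size)) < 0.02
    if not mask.any():
        mask[int(r0), int(c0)] = True
    return mask.astype(np.uint8)


# -------------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def tiny_samples():
    """12 standardized 32x32 synthetic samples (4 per class)."""
    scene = SceneParams(image_size=32, seed=7)
    return [standardize(s, 32) for s in make_dataset(4, scene)]


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """The same micro dataset written to disk in the standard layout."""
    from ifrcnet.synthetic_data import write_dataset

    scene = SceneParams(image_size=32, seed=7)
    samples = make_dataset(4, scene)
    out = tmp_path_factory.mktemp("data") / "tiny"
    write_dataset(samples, out, scene)
    return out
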