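"""RCA-UNet: the tongue segmentation network.

A four-stage U-Net whose encoder stages are dual 3x3 convolutions
(conv-BN-ReLU twice) followed by RCBAM and 2x2 max pooling, whose skip
connections are gated by MSAG, and whose decoder upsamples with 2x2 stride-2
transposed convolutions. The head is a 1x1 convolution to two logit channels
(background / tongue); the predicted mask is the per-pixel argmax.

Encoder feature maps (four stage outputs plus the bottleneck, deepest last)
are retained in the output so the classification network can fuse them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention_blocks import MSAG, RCBAM
from .errors import ShapeError
from .nn import Tensor

__all__ = ["SegNetConfig", "SegOutput", "DualConv", "RCAUNet", "seg_loss"]


@dataclass
class SegNetConfig:
    in_channels: int = 3
    base_width: int = 64
    depth: int = 4          # fixed: four downsamplings
    msag_dilation: int = 2
    rcbam_reduction: int = 16

    def __post_init__(self):
        if self.depth != 4:
            raise ValueError("RCA-UNet downsamples exactly four times (depth=4)")


@dataclass
class SegOutput:
    logits: Tensor                       # (N, 2, H, W)
    mask: np.ndarray                     # (N, H, W) in {0,1}
    encoder_features: list = field(default_factory=list)  # 5 maps, deepest last


class DualConv(nn.Module):
    """Two identical 3x3 conv -> BN -> ReLU stages; spatial size preserved."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | int | None = None):
        super().__init__()
        rng = nn.default_rng(rng)
        self.conv1 = nn.Conv2d(in_channels, out_channels, 3, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_channels)
        self.conv2 = nn.Conv2d(out_channels, out_channels, 3, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class RCAUNet(nn.Module):
    """Segmentation network; see module docstring for the layout."""

    def __init__(self, cfg: SegNetConfig | None = None, seed: int | None = 0):
        super().__init__()
        cfg = cfg or SegNetConfig()
        rng = nn.default_rng(seed)
        self.cfg = cfg
        w = cfg.base_width
        widths = [w * (2 ** i) for i in range(cfg.depth)]        # encoder stages
        self.widths = widths + [w * (2 ** cfg.depth)]            # + bottleneck

        ins = [cfg.in_channels] + widths[:-1]
        for i, (ci, co) in enumerate(zip(ins, widths)):
            setattr(self, f"enc{i}", DualConv(ci, co, rng=rng))
            setattr(self, f"enc_att{i}", RCBAM(co, cfg.rcbam_reduction, rng=rng))
            setattr(self, f"skip_gate{i}", MSAG(co, cfg.msag_dilation, rng=rng))
        self.bottleneck = DualConv(widths[-1], self.widths[-1], rng=rng)
        for i in reversed(range(cfg.depth)):
            up_in = self.widths[i + 1]
            setattr(self, f"up{i}", nn.ConvTranspose2d(up_in, widths[i], rng=rng))
            setattr(self, f"dec{i}", DualConv(2 * widths[i], widths[i], rng=rng))
        self.head = nn.Conv2d(widths[0], 2, 1, rng=rng)

    def forward(self, x: Tensor) -> SegOutput:
        n, c, h, w = x.shape
        if h % 16 or w % 16:
            raise ShapeError(f"input spatial size {h}x{w} must be divisible by 16")
        skips, features = [], []
        for i in range(self.cfg.depth):
            x = getattr(self, f"enc_att{i}")(getattr(self, f"enc{i}")(x))
            skips.append(x)
            features.append(x)
            x = nn.max_pool2d(x)
        x = self.bottleneck(x)
        features.append(x)
        for i in reversed(range(self.cfg.depth)):
            x = getattr(self, f"up{i}")(x)
            gated = getattr(self, f"skip_gate{i}")(skips[i])
            x = getattr(self, f"dec{i}")(nn.concat([x, gated], axis=1))
        logits = self.head(x)
        mask = logits.data.argmax(axis=1).astype(np.uint8)
        return SegOutput(logits=logits, mask=mask, encoder_features=features)


def seg_loss(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Mean per-pixel two-class cross-entropy (ln 2 for uniform logits)."""
    mask = np.asarray(mask)
    n, k, h, w = logits.shape
    if k != 2:
        raise ShapeError(f"expected 2 logit channels, got {k}")
    if mask.shape != (n, h, w):
        raise ShapeError(f"mask shape {mask.shape} does not match logits {logits.shape}")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    flat = logits.reshape(n, k, h * w)
    # (N, K, P) -> (N*P, K) without a transpose op: sum over explicit gather
    flat = _to_pixels(flat, n, k, h * w)
    return nn.cross_entropy_logits(flat, mask.reshape(-1).astype(np.int64))


def _to_pixels(x: Tensor, n: int, k: int, p: int) -> Tensor:
    """(N, K, P) -> (N*P, K) keeping the autodiff graph."""
    perm = (0, 2, 1)

    def backward(g):
        x._accumulate(g.reshape(n, p, k).transpose(0, 2, 1))

    data = x.data.transpose(perm).reshape(n * p, k)
    return Tensor._result(data, (x,), backward)
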