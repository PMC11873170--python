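"""Attention blocks: RCBAM (residual channel+spatial attention) and MSAG.

RCBAM follows the CBAM arrangement — a channel attention module (CAM) whose
per-channel weights come from a shared two-layer bottleneck applied to both
globally average-pooled and max-pooled descriptors, then a spatial attention
module (SAM) whose per-pixel weights come from a k x k convolution over the
channel-mean/channel-max planes — wrapped in a residual branch:

    out = x + (x * CAM(x)) * SAM(x * CAM(x))

so that with saturated-closed gates the block passes its input through
unchanged, and with fully-open gates it doubles it.

MSAG (multiscale attention gate) filters a skip feature through three parallel
convolutions (pointwise, ordinary 3x3, dilated 3x3), concatenates and
normalizes them, reduces the 3C stack with a 1x1 "vote" convolution to a
per-pixel sigmoid gate g, and returns x + x*g.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import ParameterError
from .nn import Tensor

__all__ = ["ChannelAttention", "SpatialAttention", "RCBAM", "MSAG",
           "channel_attention", "spatial_attention"]


class ChannelAttention(nn.Module):
    """Per-channel sigmoid weights, constant over space, broadcast to x's shape."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | int | None = None):
        super().__init__()
        rng = nn.default_rng(rng)
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))          # (N, C)
        mx = x.max(axis=(2, 3))            # (N, C)
        scores = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        w = scores.sigmoid().reshape(x.shape[0], self.channels, 1, 1)
        return w * Tensor(np.ones((1, 1) + tuple(x.shape[2:]), dtype=x.dtype))


class SpatialAttention(nn.Module):
    """Per-pixel sigmoid weights from a kxk conv over [channel-mean, channel-max]."""

    def __init__(self, kernel: int = 7, rng: np.random.Generator | int | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ParameterError(f"spatial attention kernel must be odd, got {kernel}")
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        mean_plane = x.mean(axis=1, keepdims=True)
        max_plane = x.max(axis=1, keepdims=True)
        stacked = nn.concat([mean_plane, max_plane], axis=1)
        return self.conv(stacked).sigmoid()   # (N, 1, H, W)


class RCBAM(nn.Module):
    """Residual CBAM: channel attention, then spatial attention, plus identity."""

    def __init__(self, channels: int, reduction: int = 16, spatial_kernel: int = 7,
                 rng: np.random.Generator | int | None = None):
        super().__init__()
        rng = nn.default_rng(rng)
        self.cam = ChannelAttention(channels, reduction, rng=rng)
        self.sam = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        xc = x * self.cam(x)
        return x + xc * self.sam(xc)


class MSAG(nn.Module):
    """Multiscale attention gate for skip connections."""

    def __init__(self, channels: int, dilation: int = 2,
                 rng: np.random.Generator | int | None = None):
        super().__init__()
        rng = nn.default_rng(rng)
        self.pointwise = nn.Conv2d(channels, channels, 1, rng=rng)
        self.ordinary = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.dilated = nn.Conv2d(channels, channels, 3, padding=dilation,
                                 dilation=dilation, rng=rng)
        self.bn = nn.BatchNorm2d(3 * channels)
        self.vote = nn.Conv2d(3 * channels, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        branches = nn.concat([self.pointwise(x), self.ordinary(x), self.dilated(x)],
                             axis=1)
        gate = self.vote(self.bn(branches).relu()).sigmoid()  # (N, 1, H, W)
        return x + x * gate


def channel_attention(x: Tensor, reduction: int = 16,
                      rng: np.random.Generator | int | None = None) -> Tensor:
    """Functional form: fresh CAM weights applied to `x` (mainly for probing)."""
    return ChannelAttention(x.shape[1], reduction, rng=rng)(x)


def spatial_attention(x: Tensor, kernel: int = 7,
                      rng: np.random.Generator | int | None = None) -> Tensor:
    """Functional form: fresh SAM weights applied to `x` (mainly for probing)."""
    return SpatialAttention(kernel, rng=rng)(x)
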