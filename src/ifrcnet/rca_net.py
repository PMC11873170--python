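"""RCA-Net: the tongue-shape classification backbone.

Five convolutional blocks (3x3 conv -> BN -> ReLU -> RCBAM); the first two use
dilated convolutions (factors 3 and 2) to widen the receptive field without
pooling, so shallow detail survives the stem. A side branch (RCBAM + max pool,
with a 1x1 projection for channel compatibility) taps the first block's output
and is merged into the main path after the second block's pooling. 2x2 max
pools follow blocks 2-5, adaptive average pooling collapses the final map to a
vector, and a three-layer fully connected classifier (512 -> 512 -> 3 by
default, with ReLU + dropout between layers) produces the class logits for
thin / normal / bulgy.

An optional fused feature vector (from the segmentation encoder; see
:mod:`ifrcnet.if_rcnet`) is concatenated to the pooled backbone vector before
the first fully connected layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .attention_blocks import RCBAM
from .errors import ShapeError
from .nn import Tensor

__all__ = ["ClsNetConfig", "ConvBlock", "RCANet", "cls_loss"]


@dataclass
class ClsNetConfig:
    in_channels: int = 3                       # 4 with mask-channel mixed input
    widths: tuple = (32, 64, 128, 256, 512)
    dilations: tuple = (3, 2, 1, 1, 1)
    fc_nodes: tuple = (512, 512, 3)
    dropout_rate: float = 0.5
    rcbam_reduction: int = 16
    branch_merge: str = "add"                  # or "concat"
    fusion_width: int = 0                      # >0 when encoder features are fused

    def __post_init__(self):
        self.widths = tuple(self.widths)
        self.dilations = tuple(self.dilations)
        self.fc_nodes = tuple(self.fc_nodes)
        if len(self.widths) != 5 or len(self.dilations) != 5:
            raise ValueError("RCA-Net has exactly five convolutional blocks")
        if self.dilations[:2] != (3, 2):
            raise ValueError("the first two blocks use dilation factors 3 and 2")
        if len(self.fc_nodes) != 3 or self.fc_nodes[-1] != 3:
            raise ValueError("the classifier is three FC layers ending in 3 nodes")
        if self.branch_merge not in ("add", "concat"):
            raise ValueError(f"unknown branch_merge {self.branch_merge!r}")


class ConvBlock(nn.Module):
    """3x3 (possibly dilated) conv -> BN -> ReLU -> RCBAM; size-preserving."""

    def __init__(self, in_channels: int, out_channels: int, dilation: int = 1,
                 reduction: int = 16, rng: np.random.Generator | int | None = None):
        super().__init__()
        rng = nn.default_rng(rng)
        self.conv = nn.Conv2d(in_channels, out_channels, 3,
                              padding=dilation, dilation=dilation, rng=rng)
        self.bn = nn.BatchNorm2d(out_channels)
        self.att = RCBAM(out_channels, reduction, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.att(self.bn(self.conv(x)).relu())


class RCANet(nn.Module):
    """Classification network; see module docstring for the layout."""

    def __init__(self, cfg: ClsNetConfig | None = None, seed: int | None = 0):
        super().__init__()
        cfg = cfg or ClsNetConfig()
        rng = nn.default_rng(seed)
        self.cfg = cfg
        w = cfg.widths
        ins = [cfg.in_channels] + list(w[:-1])
        if cfg.branch_merge == "concat":
            ins[2] = w[1] + w[1]   # block 3 sees main + branch stacks
        for i in range(5):
            setattr(self, f"block{i}",
                    ConvBlock(ins[i], w[i], cfg.dilations[i], cfg.rcbam_reduction,
                              rng=rng))
        self.branch_att = RCBAM(w[0], cfg.rcbam_reduction, rng=rng)
        self.branch_proj = nn.Conv2d(w[0], w[1], 1, rng=rng)
        feat = w[4] + cfg.fusion_width
        self.fc1 = nn.Linear(feat, cfg.fc_nodes[0], rng=rng)
        self.fc2 = nn.Linear(cfg.fc_nodes[0], cfg.fc_nodes[1], rng=rng)
        self.fc3 = nn.Linear(cfg.fc_nodes[1], cfg.fc_nodes[2], rng=rng)
        self.drop1 = nn.Dropout(cfg.dropout_rate, rng=rng)
        self.drop2 = nn.Dropout(cfg.dropout_rate, rng=rng)

    def forward(self, x: Tensor, fused: Tensor | None = None) -> Tensor:
        if (fused is None) != (self.cfg.fusion_width == 0):
            raise ShapeError("fused vector presence must match cfg.fusion_width")
        if fused is not None and fused.shape[1] != self.cfg.fusion_width:
            raise ShapeError(
                f"fused width {fused.shape[1]} != configured {self.cfg.fusion_width}")
        b1 = self.block0(x)
        branch = self.branch_proj(nn.max_pool2d(self.branch_att(b1)))
        main = nn.max_pool2d(self.block1(b1))
        if self.cfg.branch_merge == "add":
            main = main + branch
        else:
            main = nn.concat([main, branch], axis=1)
        for i in (2, 3, 4):
            main = nn.max_pool2d(getattr(self, f"block{i}")(main))
        vec = nn.global_avg_pool(main)                     # adaptive avg pool to 1x1
        if fused is not None:
            vec = nn.concat([vec, fused], axis=1)
        h = self.drop1(self.fc1(vec).relu())
        h = self.drop2(self.fc2(h).relu())
        return self.fc3(h)


def cls_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean three-class cross-entropy (ln 3 for uniform logits)."""
    labels = np.asarray(labels)
    if logits.ndim != 2 or logits.shape[1] != 3:
        raise ShapeError(f"expected (batch, 3) logits, got {logits.shape}")
    if labels.size and (labels.min() < 0 or labels.max() > 2):
        raise ValueError("labels must lie in {0, 1, 2}")
    return nn.cross_entropy_logits(logits, labels.astype(np.int64))
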