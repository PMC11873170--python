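"""IF-RCNet: the two-level nesting of RCA-UNet into RCA-Net.

Two couplings connect the segmentation network to the classifier:

* **mixed input** — the predicted tongue mask (soft foreground probability by
  default) is combined with the original RGB image before it enters RCA-Net,
  either as a fourth channel (``mask_channel``) or as a masked RGB copy
  stacked with the original (``masked_rgb_concat``, six channels);
* **feature fusion** — one encoder feature map of RCA-UNet (the deepest by
  default) is projected by a 1x1 convolution, average-pooled to a vector, and
  concatenated to RCA-Net's pooled backbone vector ahead of the classifier
  head.

With both couplings disabled the model is parameter-identical to a standalone
RCA-Net, which is the baseline row of the ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigError, ParameterError, ShapeError
from .nn import Tensor
from .rca_net import ClsNetConfig, RCANet
from .rca_unet import RCAUNet, SegOutput

__all__ = ["FusionConfig", "FeatureFusion", "IFRCNet", "mixed_input",
           "fuse_features", "build_ifrcnet"]

_MIX_CHANNELS = {"mask_channel": 4, "masked_rgb_concat": 6}


@dataclass
class FusionConfig:
    use_mixed: bool = True
    use_fusion: bool = True
    mix_mode: str = "mask_channel"      # or "masked_rgb_concat"
    fusion_stage: int = -1              # index into encoder_features; deepest
    fusion_width: int = 128
    freeze_seg: bool = True
    soft_mask: bool = True              # softmax foreground probability vs argmax

    def __post_init__(self):
        if self.mix_mode not in _MIX_CHANNELS:
            raise ConfigError(f"unknown mix_mode {self.mix_mode!r}")

    @property
    def cls_in_channels(self) -> int:
        return _MIX_CHANNELS[self.mix_mode] if self.use_mixed else 3


def _foreground_prob(seg: SegOutput, cfg: FusionConfig) -> Tensor:
    logits = seg.logits.detach() if cfg.freeze_seg else seg.logits
    if not cfg.soft_mask:
        return Tensor(seg.mask[:, None].astype(logits.dtype))
    n, _, h, w = logits.shape
    # binary softmax foreground probability = sigmoid(z1 - z0)
    z = logits.reshape(n, 2, h * w)
    diff = _channel_diff(z).reshape(n, 1, h, w)
    return diff.sigmoid()


def _channel_diff(z: Tensor) -> Tensor:
    """(N, 2, P) -> (N, P): channel 1 minus channel 0, autodiff-aware."""
    def backward(g):
        gz = np.stack([-g, g], axis=1)
        z._accumulate(gz)

    return Tensor._result(z.data[:, 1] - z.data[:, 0], (z,), backward)


def mixed_input(image_batch: Tensor, seg: SegOutput, cfg: FusionConfig) -> Tensor:
    """Combine the image with the predicted mask per ``cfg.mix_mode``."""
    n, c, h, w = image_batch.shape
    if seg.logits.shape[0] != n or seg.logits.shape[2:] != (h, w):
        raise ShapeError(
            f"segmentation output {seg.logits.shape} misaligned with images "
            f"{image_batch.shape}")
    prob = _foreground_prob(seg, cfg)
    if cfg.mix_mode == "mask_channel":
        return nn.concat([image_batch, prob], axis=1)
    masked = image_batch * prob
    return nn.concat([masked, image_batch], axis=1)


class FeatureFusion(nn.Module):
    """1x1 projection + global average pooling of one encoder feature map."""

    def __init__(self, in_channels: int, fusion_width: int = 128,
                 rng: np.random.Generator | int | None = None):
        super().__init__()
        self.proj = nn.Conv2d(in_channels, fusion_width, 1, rng=rng)
        self.fusion_width = fusion_width

    def forward(self, feature_map: Tensor) -> Tensor:
        return nn.global_avg_pool(self.proj(feature_map))   # (N, fusion_width)


def fuse_features(encoder_features: list, fusion: FeatureFusion,
                  stage: int = -1, freeze: bool = True) -> Tensor:
    """Select one encoder stage and reduce it to a fixed-length vector."""
    try:
        fmap = encoder_features[stage]
    except IndexError as exc:
        raise ParameterError(
            f"fusion_stage {stage} out of range for {len(encoder_features)} "
            f"encoder features") from exc
    if freeze:
        fmap = fmap.detach()
    return fusion(fmap)


class IFRCNet(nn.Module):
    """The nested segmentation-then-classification model."""

    def __init__(self, seg_net: RCAUNet, cls_net: RCANet, cfg: FusionConfig,
                 seed: int | None = 0):
        super().__init__()
        expected_in = cfg.cls_in_channels
        if cls_net.cfg.in_channels != expected_in:
            raise ConfigError(
                f"cls_net expects {cls_net.cfg.in_channels} input channels but "
                f"mix_mode/use_mixed requires {expected_in}")
        expected_fusion = cfg.fusion_width if cfg.use_fusion else 0
        if cls_net.cfg.fusion_width != expected_fusion:
            raise ConfigError(
                f"cls_net fusion_width {cls_net.cfg.fusion_width} but fusion "
                f"config requires {expected_fusion}")
        self.seg_net = seg_net
        self.cls_net = cls_net
        self.cfg = cfg
        if cfg.use_fusion:
            stage_channels = seg_net.widths[cfg.fusion_stage]
            self.fusion = FeatureFusion(stage_channels, cfg.fusion_width,
                                        rng=nn.default_rng(seed))
        else:
            self.fusion = None

    def train(self, mode: bool = True):
        super().train(mode)
        if mode and self.cfg.freeze_seg:
            # frozen segmentation net stays in eval mode (running BN statistics)
            self.seg_net.eval()
        return self

    def classifier_parameters(self):
        """Parameters updated in the classification phase (seg net excluded
        when frozen)."""
        yield from self.cls_net.parameters()
        if self.fusion is not None:
            yield from self.fusion.parameters()
        if not self.cfg.freeze_seg:
            yield from self.seg_net.parameters()

    def forward(self, image_batch: Tensor) -> Tensor:
        cfg = self.cfg
        if not cfg.use_mixed and not cfg.use_fusion:
            return self.cls_net(image_batch)
        if cfg.freeze_seg:
            with nn.no_grad():
                seg = self.seg_net(image_batch)
        else:
            seg = self.seg_net(image_batch)
        x = mixed_input(image_batch, seg, cfg) if cfg.use_mixed else image_batch
        fused = None
        if cfg.use_fusion:
            fused = fuse_features(seg.encoder_features, self.fusion,
                                  cfg.fusion_stage, cfg.freeze_seg)
        return self.cls_net(x, fused=fused)


def build_ifrcnet(seg_net: RCAUNet, ablation: str = "both",
                  cls_cfg: ClsNetConfig | None = None,
                  fusion_cfg: FusionConfig | None = None,
                  seed: int | None = 0) -> IFRCNet:
    """Build one of the four ablation configurations: base/mixed/fusion/both."""
    if ablation not in ("base", "mixed", "fusion", "both"):
        raise ConfigError(f"unknown ablation {ablation!r}")
    fusion_cfg = fusion_cfg or FusionConfig()
    cfg = FusionConfig(
        use_mixed=ablation in ("mixed", "both"),
        use_fusion=ablation in ("fusion", "both"),
        mix_mode=fusion_cfg.mix_mode,
        fusion_stage=fusion_cfg.fusion_stage,
        fusion_width=fusion_cfg.fusion_width,
        freeze_seg=fusion_cfg.freeze_seg,
        soft_mask=fusion_cfg.soft_mask,
    )
    base = cls_cfg or ClsNetConfig()
    from dataclasses import replace
    cls_net = RCANet(replace(base, in_channels=cfg.cls_in_channels,
                             fusion_width=cfg.fusion_width if cfg.use_fusion else 0),
                     seed=seed)
    return IFRCNet(seg_net, cls_net, cfg, seed=seed)
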