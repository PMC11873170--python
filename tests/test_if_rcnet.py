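"""IF-RCNet couplings: mixed input, feature fusion, ablation parity, config."""

import numpy as np
import pytest

from ifrcnet import nn
from ifrcnet.errors import ConfigError, ParameterError, ShapeError
from ifrcnet.if_rcnet import (FeatureFusion, FusionConfig, IFRCNet, build_ifrcnet,
                              fuse_features, mixed_input)
from ifrcnet.nn import Tensor
from ifrcnet.rca_net import ClsNetConfig, RCANet
from ifrcnet.rca_unet import RCAUNet, SegNetConfig

TINY_CLS = dict(widths=(4, 4, 8, 8, 8), fc_nodes=(16, 16, 3))


@pytest.fixture(scope="module")
def seg_net():
    return RCAUNet(SegNetConfig(base_width=4), seed=0).eval()


@pytest.fixture(scope="module")
def seg_out(seg_net):
    x = Tensor(np.random.default_rng(0).normal(size=(2, 3, 32, 32))
               .astype(np.float32))
    with nn.no_grad():
        return x, seg_net(x)


def test_mixed_input_mask_channel_is_sigmoid_of_logit_difference(seg_out):
    x, seg = seg_out
    mixed = mixed_input(x, seg, FusionConfig(mix_mode="mask_channel"))
    assert mixed.shape == (2, 4, 32, 32)
    assert np.array_equal(mixed.data[:, :3], x.data)
    z = seg.logits.data
    want = 1.0 / (1.0 + np.exp(-(z[:, 1] - z[:, 0])))
    assert np.allclose(mixed.data[:, 3], want, atol=1e-6)


def test_mixed_input_hard_mask_uses_the_argmax_mask(seg_out):
    x, seg = seg_out
    mixed = mixed_input(x, seg, FusionConfig(soft_mask=False))
    assert np.array_equal(mixed.data[:, 3], seg.mask.astype(np.float64))


def test_mixed_input_masked_rgb_concat_mode(seg_out):
    x, seg = seg_out
    cfg = FusionConfig(mix_mode="masked_rgb_concat")
    mixed = mixed_input(x, seg, cfg)
    assert mixed.shape == (2, 6, 32, 32)
    z = seg.logits.data
    prob = 1.0 / (1.0 + np.exp(-(z[:, 1] - z[:, 0])))
    assert np.allclose(mixed.data[:, :3], x.data * prob[:, None], atol=1e-6)
    assert np.array_equal(mixed.data[:, 3:], x.data)


def test_mixed_input_rejects_misaligned_segmentation(seg_out):
    x, seg = seg_out
    small = Tensor(np.zeros((2, 3, 16, 16)))
    with pytest.raises(ShapeError):
        mixed_input(small, seg, FusionConfig())


def test_fusion_config_rejects_unknown_mix_mode():
    with pytest.raises(ConfigError):
        FusionConfig(mix_mode="alpha_blend")


def test_fuse_features_pools_the_selected_stage(seg_out):
    _, seg = seg_out
    fusion = FeatureFusion(in_channels=64, fusion_width=8, rng=0)
    vec = fuse_features(seg.encoder_features, fusion, stage=-1)
    assert vec.shape == (2, 8)
    # oracle: 1x1 conv is a channel-mixing matmul, then spatial mean
    fmap = seg.encoder_features[-1].data
    w = fusion.proj.weight.data[:, :, 0, 0]
    b = fusion.proj.bias.data
    want = (np.einsum("nchw,oc->nohw", fmap, w)
            + b[None, :, None, None]).mean(axis=(2, 3))
    assert np.allclose(vec.data, want, atol=1e-5)


def test_fuse_features_rejects_out_of_range_stage(seg_out):
    _, seg = seg_out
    fusion = FeatureFusion(in_channels=64, fusion_width=8, rng=0)
    with pytest.raises(ParameterError):
        fuse_features(seg.encoder_features, fusion, stage=7)


def test_base_ablation_is_parameter_identical_to_standalone_rcanet(seg_net):
    cls_cfg = ClsNetConfig(**TINY_CLS)
    nested = build_ifrcnet(seg_net, "base", cls_cfg=cls_cfg, seed=5).eval()
    standalone = RCANet(cls_cfg, seed=5).eval()
    a = dict(nested.cls_net.named_parameters())
    b = dict(standalone.named_parameters())
    assert a.keys() == b.keys()
    for k in a:
        assert np.array_equal(a[k].data, b[k].data), k
    x = Tensor(np.random.default_rng(1).normal(size=(2, 3, 32, 32))
               .astype(np.float32))
    with nn.no_grad():
        assert np.array_equal(nested(x).data, standalone(x).data)


def test_ablation_lattice_output_shapes(seg_net):
    x = Tensor(np.random.default_rng(2).normal(size=(2, 3, 32, 32))
               .astype(np.float32))
    for ablation in ("base", "mixed", "fusion", "both"):
        model = build_ifrcnet(seg_net, ablation, cls_cfg=ClsNetConfig(**TINY_CLS),
                              fusion_cfg=FusionConfig(fusion_width=8),
                              seed=0).eval()
        with nn.no_grad():
            assert model(x).shape == (2, 3), ablation


def test_build_rejects_unknown_ablation(seg_net):
    with pytest.raises(ConfigError):
        build_ifrcnet(seg_net, "everything")


def test_ifrcnet_rejects_channel_and_fusion_mismatch(seg_net):
    cfg = FusionConfig(use_mixed=True, use_fusion=False)
    with pytest.raises(ConfigError):
        IFRCNet(seg_net, RCANet(ClsNetConfig(in_channels=3, **TINY_CLS)), cfg)
    cfg2 = FusionConfig(use_mixed=False, use_fusion=True, fusion_width=8)
    with pytest.raises(ConfigError):
        IFRCNet(seg_net, RCANet(ClsNetConfig(in_channels=3, fusion_width=4,
                                             **TINY_CLS)), cfg2)


def test_frozen_seg_net_stays_in_eval_mode_during_training(seg_net):
    model = build_ifrcnet(seg_net, "both", cls_cfg=ClsNetConfig(**TINY_CLS),
                          fusion_cfg=FusionConfig(fusion_width=8), seed=0)
    model.train()
    assert model.cls_net.training
    assert not model.seg_net.training
    assert all(not m.training for m in model.seg_net.modules())


def test_classifier_parameters_exclude_frozen_seg_net(seg_net):
    model = build_ifrcnet(seg_net, "both", cls_cfg=ClsNetConfig(**TINY_CLS),
                          fusion_cfg=FusionConfig(fusion_width=8), seed=0)
    trainable = {id(p) for p in model.classifier_parameters()}
    seg_params = {id(p) for p in model.seg_net.parameters()}
    fusion_params = {id(p) for p in model.fusion.parameters()}
    assert not (trainable & seg_params)
    assert fusion_params <= trainable


def test_gradients_do_not_reach_a_frozen_seg_net(seg_net):
    model = build_ifrcnet(seg_net, "both", cls_cfg=ClsNetConfig(**TINY_CLS),
                          fusion_cfg=FusionConfig(fusion_width=8), seed=0)
    model.train()
    model.zero_grad()
    x = Tensor(np.random.default_rng(3).normal(size=(2, 3, 32, 32))
               .astype(np.float32))
    (model(x) ** 2).sum().backward()
    assert all(p.grad is None for p in model.seg_net.parameters())
    assert any(p.grad is not None for p in model.cls_net.parameters())
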