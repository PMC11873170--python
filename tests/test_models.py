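"""RCA-UNet and RCA-Net: shape contracts, loss values, behavioural probes."""

import numpy as np
import pytest

from ifrcnet import nn
from ifrcnet.errors import ShapeError
from ifrcnet.nn import Tensor
from ifrcnet.rca_net import ClsNetConfig, RCANet, cls_loss
from ifrcnet.rca_unet import RCAUNet, SegNetConfig, seg_loss

TINY_CLS = dict(widths=(4, 4, 8, 8, 8), fc_nodes=(16, 16, 3))


def test_seg_net_shape_contract_and_encoder_widths():
    model = RCAUNet(SegNetConfig(base_width=4), seed=0).eval()
    assert model.widths == [4, 8, 16, 32, 64]
    x = Tensor(np.random.default_rng(0).normal(size=(2, 3, 32, 32)))
    with nn.no_grad():
        out = model(x)
    assert out.logits.shape == (2, 2, 32, 32)
    assert out.mask.shape == (2, 32, 32)
    assert set(np.unique(out.mask)) <= {0, 1}
    # five encoder maps, deepest last, halving resolution and doubling width
    assert [f.shape[1] for f in out.encoder_features] == [4, 8, 16, 32, 64]
    assert [f.shape[2] for f in out.encoder_features] == [32, 16, 8, 4, 2]


def test_seg_net_rejects_indivisible_sizes():
    model = RCAUNet(SegNetConfig(base_width=4), seed=0)
    with pytest.raises(ShapeError):
        model(Tensor(np.zeros((1, 3, 30, 32))))


def test_seg_config_depth_is_fixed():
    with pytest.raises(ValueError):
        SegNetConfig(depth=3)


def test_seg_loss_is_ln2_for_uniform_logits():
    logits = Tensor(np.zeros((2, 2, 4, 4)))
    mask = np.random.default_rng(0).integers(0, 2, (2, 4, 4))
    assert np.isclose(float(seg_loss(logits, mask).data), np.log(2.0))


def test_seg_loss_validates_inputs():
    with pytest.raises(ShapeError):
        seg_loss(Tensor(np.zeros((1, 3, 4, 4))), np.zeros((1, 4, 4)))
    with pytest.raises(ShapeError):
        seg_loss(Tensor(np.zeros((1, 2, 4, 4))), np.zeros((1, 5, 5)))
    with pytest.raises(ValueError):
        seg_loss(Tensor(np.zeros((1, 2, 2, 2))), np.full((1, 2, 2), 7))


def test_seg_logit_flip_flips_the_mask():
    model = RCAUNet(SegNetConfig(base_width=4), seed=1).eval()
    x = Tensor(np.random.default_rng(1).normal(size=(1, 3, 32, 32)))
    with nn.no_grad():
        out = model(x)
    z = out.logits.data
    flipped = z[:, ::-1].argmax(axis=1)
    untied = z[:, 0] != z[:, 1]   # argmax breaks exact ties towards class 0
    assert untied.any()
    assert np.array_equal(flipped[untied], 1 - out.mask[untied])


def test_cls_net_shape_contract():
    model = RCANet(ClsNetConfig(**TINY_CLS), seed=0).eval()
    x = Tensor(np.random.default_rng(0).normal(size=(2, 3, 32, 32)))
    with nn.no_grad():
        logits = model(x)
    assert logits.shape == (2, 3)


def test_cls_config_validation():
    with pytest.raises(ValueError):
        ClsNetConfig(widths=(4, 4, 4))                     # not five blocks
    with pytest.raises(ValueError):
        ClsNetConfig(dilations=(1, 1, 1, 1, 1))            # stem must be 3, 2
    with pytest.raises(ValueError):
        ClsNetConfig(fc_nodes=(16, 16, 4))                 # head must end in 3
    with pytest.raises(ValueError):
        ClsNetConfig(branch_merge="multiply")
    cfg = ClsNetConfig(widths=[4, 4, 8, 8, 8], dilations=[3, 2, 1, 1, 1],
                       fc_nodes=[16, 16, 3])               # lists are coerced
    assert cfg.widths == (4, 4, 8, 8, 8)


def test_cls_loss_is_ln3_for_uniform_logits():
    assert np.isclose(float(cls_loss(Tensor(np.zeros((4, 3))),
                                     np.array([0, 1, 2, 0])).data), np.log(3.0))


def test_cls_fused_vector_contract():
    model = RCANet(ClsNetConfig(fusion_width=8, **TINY_CLS), seed=0).eval()
    x = Tensor(np.random.default_rng(0).normal(size=(1, 3, 32, 32)))
    with pytest.raises(ShapeError):
        model(x)                                           # fused required
    with pytest.raises(ShapeError):
        model(x, fused=Tensor(np.zeros((1, 5))))           # wrong width
    with nn.no_grad():
        assert model(x, fused=Tensor(np.zeros((1, 8)))).shape == (1, 3)
    plain = RCANet(ClsNetConfig(**TINY_CLS), seed=0).eval()
    with pytest.raises(ShapeError):
        plain(x, fused=Tensor(np.zeros((1, 8))))           # unexpected fused


def test_dilated_stem_receptive_field_probe():
    """A single distant pixel influences block0's centre output only under
    dilation 3 (kernel span 7), not under an undilated 3x3 kernel."""
    cfg = ClsNetConfig(**TINY_CLS)
    model = RCANet(cfg, seed=0).eval()
    conv = model.block0.conv
    x0 = np.zeros((1, 3, 9, 9), dtype=np.float32)
    x1 = x0.copy()
    x1[0, 0, 1, 1] = 5.0    # offset 3 from the centre: inside span 7, outside 3
    with nn.no_grad():
        d0 = conv(Tensor(x0)).data[0, :, 4, 4]
        d1 = conv(Tensor(x1)).data[0, :, 4, 4]
    assert not np.allclose(d0, d1)
    plain = nn.Conv2d(3, 4, 3, padding=1, rng=0)
    with nn.no_grad():
        p0 = plain(Tensor(x0)).data[0, :, 4, 4]
        p1 = plain(Tensor(x1)).data[0, :, 4, 4]
    assert np.allclose(p0, p1)


def test_cls_net_is_batch_permutation_equivariant():
    model = RCANet(ClsNetConfig(**TINY_CLS), seed=2).eval()
    x = np.random.default_rng(2).normal(size=(4, 3, 32, 32)).astype(np.float32)
    perm = np.array([2, 0, 3, 1])
    with nn.no_grad():
        straight = model(Tensor(x)).data
        permuted = model(Tensor(x[perm])).data
    assert np.allclose(straight[perm], permuted, atol=1e-5)


def test_branch_concat_merge_also_builds_and_runs():
    cfg = ClsNetConfig(branch_merge="concat", **TINY_CLS)
    model = RCANet(cfg, seed=0).eval()
    x = Tensor(np.random.default_rng(0).normal(size=(1, 3, 32, 32)))
    with nn.no_grad():
        assert model(x).shape == (1, 3)


def test_models_train_mode_changes_dropout_only_not_output_shape():
    model = RCANet(ClsNetConfig(**TINY_CLS), seed=3)
    x = Tensor(np.random.default_rng(3).normal(size=(2, 3, 32, 32)))
    model.train()
    with nn.no_grad():
        a = model(x)
    assert a.shape == (2, 3)
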