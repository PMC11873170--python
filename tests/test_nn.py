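"""Autodiff core: gradient checks against finite differences and naive oracles."""

import numpy as np
import pytest

from conftest import naive_conv2d, numeric_grad
from ifrcnet import nn
from ifrcnet.nn import Tensor


def test_elementwise_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    a0 = rng.normal(size=(3, 4))
    b0 = rng.normal(size=(3, 4)) + 3.0

    def f(av):
        a = Tensor(av, requires_grad=True)
        b = Tensor(b0, requires_grad=True)
        return float((((a * b + 2.0) / b - a.relu()) ** 2).sum().data)

    a = Tensor(a0, requires_grad=True)
    b = Tensor(b0, requires_grad=True)
    out = ((a * b + 2.0) / b - a.relu()) ** 2
    out.sum().backward()
    assert np.allclose(a.grad, numeric_grad(f, a0.copy()), atol=1e-6)


def test_broadcast_gradient_sums_over_broadcast_axes():
    a = Tensor(np.ones((2, 3, 4)), requires_grad=True)
    b = Tensor(np.arange(4.0), requires_grad=True)
    (a * b).sum().backward()
    assert np.allclose(b.grad, np.full(4, 6.0))   # 2*3 copies each
    assert np.allclose(a.grad, np.broadcast_to(np.arange(4.0), (2, 3, 4)))


def test_matmul_sigmoid_log_exp_gradients():
    rng = np.random.default_rng(1)
    x0 = rng.normal(size=(3, 5))
    w0 = rng.normal(size=(5, 2))

    def f(xv):
        x = Tensor(xv, requires_grad=True)
        return float(((x @ Tensor(w0)).sigmoid().exp().log()).sum().data)

    x = Tensor(x0, requires_grad=True)
    (x @ Tensor(w0)).sigmoid().exp().log().sum().backward()
    assert np.allclose(x.grad, numeric_grad(f, x0.copy()), atol=1e-6)


def test_max_gradient_splits_ties_evenly():
    x = Tensor(np.array([[1.0, 3.0, 3.0]]), requires_grad=True)
    x.max(axis=1).sum().backward()
    assert np.allclose(x.grad, [[0.0, 0.5, 0.5]])


def test_mean_and_reshape_gradients():
    x = Tensor(np.arange(12.0).reshape(3, 4), requires_grad=True)
    x.reshape(2, 6).mean().backward()
    assert np.allclose(x.grad, np.full((3, 4), 1.0 / 12))


def test_concat_routes_gradient_to_parts():
    a = Tensor(np.ones((2, 2)), requires_grad=True)
    b = Tensor(np.ones((2, 3)), requires_grad=True)
    out = nn.concat([a, b], axis=1)
    out.backward(np.arange(10.0).reshape(2, 5))
    assert np.allclose(a.grad, [[0, 1], [5, 6]])
    assert np.allclose(b.grad, [[2, 3, 4], [7, 8, 9]])


def test_conv2d_matches_naive_oracle_with_padding_and_dilation():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(2, 3, 8, 8))
    w = rng.normal(size=(4, 3, 3, 3))
    b = rng.normal(size=4)
    got = nn.conv2d(Tensor(x), Tensor(w), Tensor(b), padding=2, dilation=2)
    want = naive_conv2d(x, w, b, padding=2, dilation=2)
    assert np.allclose(got.data, want, atol=1e-10)


def test_conv2d_gradients_match_finite_differences():
    rng = np.random.default_rng(3)
    x0 = rng.normal(size=(1, 2, 5, 5))
    w0 = rng.normal(size=(3, 2, 3, 3))
    b0 = rng.normal(size=3)

    def loss(xv, wv, bv):
        out = nn.conv2d(Tensor(xv, requires_grad=True),
                        Tensor(wv, requires_grad=True),
                        Tensor(bv, requires_grad=True), padding=1)
        return float((out ** 2).sum().data)

    x = Tensor(x0, requires_grad=True)
    w = Tensor(w0, requires_grad=True)
    b = Tensor(b0, requires_grad=True)
    (nn.conv2d(x, w, b, padding=1) ** 2).sum().backward()
    assert np.allclose(x.grad, numeric_grad(lambda v: loss(v, w0, b0), x0.copy()),
                       atol=1e-5)
    assert np.allclose(w.grad, numeric_grad(lambda v: loss(x0, v, b0), w0.copy()),
                       atol=1e-5)
    assert np.allclose(b.grad, numeric_grad(lambda v: loss(x0, w0, v), b0.copy()),
                       atol=1e-5)


def test_conv_transpose_inverts_spatial_size_and_gradchecks():
    rng = np.random.default_rng(4)
    x0 = rng.normal(size=(1, 2, 3, 3))
    w0 = rng.normal(size=(2, 3, 2, 2))
    out = nn.conv_transpose2d_2x2(Tensor(x0), Tensor(w0), None)
    assert out.shape == (1, 3, 6, 6)

    def loss(xv):
        o = nn.conv_transpose2d_2x2(Tensor(xv, requires_grad=True), Tensor(w0), None)
        return float((o ** 2).sum().data)

    x = Tensor(x0, requires_grad=True)
    (nn.conv_transpose2d_2x2(x, Tensor(w0), None) ** 2).sum().backward()
    assert np.allclose(x.grad, numeric_grad(loss, x0.copy()), atol=1e-5)


def test_max_pool_selects_maxima_and_routes_gradient():
    x = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]]), requires_grad=True)
    out = nn.max_pool2d(x)
    assert out.data.item() == 4.0
    out.sum().backward()
    assert np.allclose(x.grad, [[[[0, 0], [0, 1.0]]]])


def test_cross_entropy_matches_scalar_formula_and_softmax_grad():
    logits0 = np.array([[2.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
    labels = np.array([0, 2])
    logits = Tensor(logits0, requires_grad=True)
    loss = nn.cross_entropy_logits(logits, labels)
    p = np.exp(logits0) / np.exp(logits0).sum(axis=1, keepdims=True)
    want = -np.log(p[[0, 1], labels]).mean()
    assert np.isclose(float(loss.data), want)
    loss.backward()
    onehot = np.eye(3)[labels]
    assert np.allclose(logits.grad, (p - onehot) / 2, atol=1e-12)


def test_batchnorm_normalizes_in_train_and_uses_running_stats_in_eval():
    rng = np.random.default_rng(5)
    bn = nn.BatchNorm2d(3, momentum=1.0)
    x = Tensor(rng.normal(2.0, 3.0, size=(4, 3, 5, 5)))
    y = bn(x)
    assert np.allclose(y.data.mean(axis=(0, 2, 3)), 0.0, atol=1e-6)
    assert np.allclose(y.data.std(axis=(0, 2, 3)), 1.0, atol=1e-3)
    bn.eval()
    y2 = bn(x)   # momentum 1.0: running stats equal the batch stats
    assert np.allclose(y.data, y2.data, atol=1e-4)


def test_no_grad_builds_no_graph():
    x = Tensor(np.ones(3), requires_grad=True)
    with nn.no_grad():
        y = (x * 2.0).sum()
    assert not y.requires_grad
    assert nn.grad_enabled()


def test_dropout_identity_in_eval_and_scales_in_train():
    drop = nn.Dropout(0.5, rng=0)
    x = Tensor(np.ones((200, 50)))
    y = drop(x)
    kept = y.data[y.data > 0]
    assert np.allclose(kept, 2.0)                      # inverted scaling
    assert abs(y.data.mean() - 1.0) < 0.05             # expectation preserved
    drop.eval()
    assert np.array_equal(drop(x).data, x.data)


def test_optimizers_descend_a_quadratic():
    for name in ("sgd", "adam"):
        p = nn.Parameter(np.array([5.0, -3.0]))
        opt = nn.build_optimizer(name, [p], lr=0.1)
        for _ in range(200):
            loss = (p * p).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.all(np.abs(p.data) < 1e-2), name


def test_checkpoint_roundtrip_restores_params_and_buffers(tmp_path):
    rng = np.random.default_rng(6)
    a = nn.Sequential(nn.Conv2d(2, 3, 3, padding=1, rng=rng), nn.BatchNorm2d(3))
    a(Tensor(rng.normal(size=(2, 2, 4, 4))))          # move running stats
    nn.save_checkpoint(a, tmp_path / "ck.npz", {"note": 1})
    b = nn.Sequential(nn.Conv2d(2, 3, 3, padding=1, rng=0), nn.BatchNorm2d(3))
    meta = nn.load_checkpoint(b, tmp_path / "ck.npz")
    assert meta == {"note": 1}
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb and np.array_equal(pa.data, pb.data)
    for (na, ba), (nb, bb) in zip(a.named_buffers(), b.named_buffers()):
        assert na == nb and np.array_equal(ba, bb)


def test_load_state_dict_rejects_unknown_and_mismatched_entries():
    lin = nn.Linear(2, 3)
    with pytest.raises(KeyError):
        lin.load_state_dict({"nope": np.zeros(1)})
    with pytest.raises(ValueError):
        lin.load_state_dict({"weight": np.zeros((5, 5))})
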