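"""Finite-difference gradient checks and optimizer behaviour."""

import numpy as np
import pytest

from msat import autodiff as ad
from msat.autodiff import Tensor


def numeric_grad(f, x, eps=1e-6):
    """Central finite differences of a scalar-valued f at array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x)
        x[i] = orig - eps
        fm = f(x)
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def check_grad(build, x0, rtol=1e-5, atol=1e-7):
    """build(Tensor) -> scalar Tensor; compares autodiff vs numeric grads."""
    t = Tensor(x0.copy())
    out = build(t)
    out.backward()
    num = numeric_grad(lambda x: float(build(Tensor(x)).data), x0.copy())
    np.testing.assert_allclose(t.grad, num, rtol=rtol, atol=atol)


rng = np.random.default_rng(3)
_W = rng.normal(size=(4, 3))
_D = rng.normal(size=(5, 4)) + 3.0


@pytest.mark.parametrize("op", [
    lambda t: ad.sum_(ad.mul(t, t)),
    lambda t: ad.sum_(ad.relu(t)),
    lambda t: ad.sum_(ad.sigmoid(t)),
    lambda t: ad.sum_(ad.exp(t)),
    lambda t: ad.sum_(ad.sqrt(ad.add(ad.mul(t, t), Tensor(1.0)))),
    lambda t: ad.sum_(ad.matmul(t, Tensor(_W))),
    lambda t: ad.sum_(ad.div(t, Tensor(_D))),
    lambda t: ad.mean_(ad.pow_(t, 3.0)),
    lambda t: ad.sum_(ad.reshape(t, (4, 5))),
    lambda t: ad.sum_(ad.concat([t, ad.mul(t, Tensor(2.0))], axis=0)),
])
def test_gradients_match_finite_differences(op):
    x = rng.normal(size=(5, 4)) + 0.1
    check_grad(op, x)


def test_broadcast_add_gradient():
    x = rng.normal(size=(5, 4))
    b = Tensor(rng.normal(size=(4,)))
    t = Tensor(x.copy())
    out = ad.sum_(ad.mul(ad.add(t, b), ad.add(t, b)))
    out.backward()
    # d/db sum((x+b)^2) = sum over rows of 2(x+b)
    np.testing.assert_allclose(b.grad, (2 * (x + b.data)).sum(axis=0))


def test_rows_gather_scatter_gradient():
    x = rng.normal(size=(6, 3))
    idx = np.array([0, 2, 2, 5])

    def f(t):
        return ad.sum_(ad.mul(ad.rows(t, idx), ad.rows(t, idx)))

    check_grad(f, x)


def test_segment_sum_values_and_gradient():
    x = rng.normal(size=(5, 2))
    idx = np.array([0, 0, 1, 2, 2])
    out = ad.segment_sum(Tensor(x), idx, 4)
    expected = np.zeros((4, 2))
    for e, s in enumerate(idx):
        expected[s] += x[e]
    np.testing.assert_allclose(out.data, expected)
    check_grad(lambda t: ad.sum_(ad.mul(ad.segment_sum(t, idx, 4),
                                        ad.segment_sum(t, idx, 4))), x)


def test_segment_softmax_rows_sum_to_one_per_segment():
    logits = rng.normal(size=(7, 3)) * 5
    idx = np.array([0, 0, 0, 1, 1, 3, 3])
    out = ad.segment_softmax(Tensor(logits), idx, 4).data
    for s in (0, 1, 3):
        np.testing.assert_allclose(out[idx == s].sum(axis=0), 1.0)


def test_segment_softmax_matches_dense_softmax():
    logits = rng.normal(size=(4, 1))
    idx = np.zeros(4, dtype=int)
    out = ad.segment_softmax(Tensor(logits), idx, 1).data.ravel()
    e = np.exp(logits.ravel() - logits.max())
    np.testing.assert_allclose(out, e / e.sum())


def test_segment_softmax_gradient():
    logits = rng.normal(size=(6, 2))
    idx = np.array([0, 0, 1, 1, 1, 2])
    w = rng.normal(size=(6, 2))

    def f(t):
        return ad.sum_(ad.mul(ad.segment_softmax(t, idx, 3), Tensor(w)))

    check_grad(f, logits, rtol=1e-4, atol=1e-7)


def test_layer_norm_output_and_gradient():
    x = rng.normal(size=(4, 6)) * 3 + 1
    g = Tensor(np.ones(6))
    b = Tensor(np.zeros(6))
    out = ad.layer_norm(Tensor(x), g, b).data
    np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
    np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-4)
    check_grad(lambda t: ad.sum_(ad.mul(ad.layer_norm(t, g, b),
                                        ad.layer_norm(t, g, b))), x,
               rtol=1e-4, atol=1e-6)


def test_bce_with_logits_value_and_gradient():
    s = np.array([[0.5], [-1.2], [2.0]])
    y = np.array([[1.0], [0.0], [1.0]])
    loss = ad.bce_with_logits(Tensor(s), y)
    p = 1 / (1 + np.exp(-s))
    expected = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
    np.testing.assert_allclose(float(loss.data), expected)
    t = Tensor(s.copy())
    ad.bce_with_logits(t, y).backward()
    np.testing.assert_allclose(t.grad, (p - y) / 3, rtol=1e-12)


def test_bce_with_logits_stable_at_extreme_logits():
    s = Tensor(np.array([[500.0], [-500.0]]))
    loss = ad.bce_with_logits(s, np.array([[1.0], [0.0]]))
    assert np.isfinite(loss.data)
    loss.backward()
    assert np.all(np.isfinite(s.grad))


def test_dropout_train_vs_eval():
    x = Tensor(np.ones((1000, 1)))
    out_eval = ad.dropout(x, 0.5, None, training=False)
    assert out_eval is x
    out_train = ad.dropout(x, 0.5, np.random.default_rng(0), training=True)
    kept = out_train.data != 0
    # inverted dropout preserves expectation
    assert abs(out_train.data.mean() - 1.0) < 0.1
    np.testing.assert_allclose(out_train.data[kept], 2.0)
    with pytest.raises(ValueError):
        ad.dropout(x, 0.5, None, training=True)


def test_clip_grad_norm_scales_to_max():
    p = {"a": Tensor(np.zeros(3)), "b": Tensor(np.zeros(4))}
    p["a"].grad = np.full(3, 2.0)
    p["b"].grad = np.full(4, 2.0)
    pre = ad.clip_grad_norm(p, 1.0)
    np.testing.assert_allclose(pre, np.sqrt(7 * 4.0))
    post = np.sqrt(sum(float(np.sum(t.grad ** 2)) for t in p.values()))
    np.testing.assert_allclose(post, 1.0)


def test_clip_grad_norm_no_op_below_max():
    p = {"a": Tensor(np.zeros(2))}
    p["a"].grad = np.array([0.3, 0.4])
    pre = ad.clip_grad_norm(p, 1.0)
    np.testing.assert_allclose(pre, 0.5)
    np.testing.assert_allclose(p["a"].grad, [0.3, 0.4])


def test_adamw_minimises_quadratic():
    p = {"x": Tensor(np.array([5.0]))}
    opt = ad.AdamW(p, lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        loss = ad.sum_(ad.mul(p["x"], p["x"]))
        loss.backward()
        opt.step()
    assert abs(p["x"].data.item()) < 1e-2


def test_adamw_weight_decay_shrinks_parameters():
    # with zero gradient signal, decoupled decay shrinks weights geometrically
    p = {"x": Tensor(np.array([1.0]))}
    opt = ad.AdamW(p, lr=0.1, weight_decay=0.5)
    opt.zero_grad()
    p["x"].grad = np.zeros(1)
    opt.step()
    np.testing.assert_allclose(p["x"].data.item(), 1.0 - 0.1 * 0.5)


def test_backward_accumulates_through_shared_subexpression():
    x = Tensor(np.array([3.0]))
    y = ad.mul(x, x)        # x^2
    z = ad.add(y, y)        # 2 x^2 -> dz/dx = 4x = 12
    z.backward()
    np.testing.assert_allclose(x.grad, [12.0])
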