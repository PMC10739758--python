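"""Composite objective: temperature softmax closed forms, soft dice and
cross-entropy against hand values and loop oracles, gradient checks."""

import numpy as np
import pytest

from tomaformer.losses import (LossConfig, one_hot, soft_dice_loss,
                               temperature_cross_entropy, temperature_softmax,
                               total_loss)
from tomaformer.nn.tensor import Tensor

from conftest import numeric_gradient


def test_softmax_equal_logits_is_uniform():
    logits = Tensor(np.zeros((1, 4, 2, 2)))
    p = temperature_softmax(logits, 1.5).data
    np.testing.assert_allclose(p, 0.25)


def test_softmax_large_temperature_approaches_uniform(rng):
    logits = Tensor(rng.normal(size=(1, 4, 3, 3)))
    p = temperature_softmax(logits, 1e6).data
    np.testing.assert_allclose(p, 0.25, atol=1e-4)


def test_softmax_two_class_closed_form():
    # logits (2, 0) at tau=2 -> exp(1)/(exp(1)+1)
    logits = Tensor(np.array([2.0, 0.0]).reshape(1, 2, 1, 1))
    p = temperature_softmax(logits, 2.0).data.ravel()
    e = np.exp(1.0)
    np.testing.assert_allclose(p, [e / (e + 1), 1 / (e + 1)], atol=1e-12)


def test_softmax_preserves_ordering(rng):
    logits = rng.normal(size=(1, 4, 2, 2))
    for tau in (0.5, 1.0, 3.0):
        p = temperature_softmax(Tensor(logits), tau).data
        np.testing.assert_array_equal(p.argmax(axis=1), logits.argmax(axis=1))


def test_nonpositive_temperature_rejected():
    with pytest.raises(ValueError):
        temperature_softmax(Tensor(np.zeros((1, 2, 1, 1))), 0.0)
    with pytest.raises(ValueError):
        LossConfig(tau=-1.0)


def test_one_hot_round_trip(rng):
    mask = rng.integers(0, 4, size=(2, 5, 5))
    t = one_hot(mask)
    assert t.shape == (2, 4, 5, 5)
    np.testing.assert_array_equal(t.argmax(axis=1), mask)
    np.testing.assert_allclose(t.sum(axis=1), 1.0)
    with pytest.raises(ValueError):
        one_hot(np.array([[[5]]]))


def test_dice_perfect_prediction_is_zero(rng):
    t = one_hot(rng.integers(0, 4, size=(2, 4, 4)))
    loss = soft_dice_loss(t, Tensor(t.copy())).data
    assert loss == pytest.approx(0.0, abs=1e-9)


def test_dice_disjoint_prediction_is_one():
    t = one_hot(np.zeros((1, 2, 2), dtype=int))
    pred = one_hot(np.ones((1, 2, 2), dtype=int))
    loss = soft_dice_loss(t, Tensor(pred)).data
    assert loss == pytest.approx(1.0, abs=1e-9)


def test_dice_two_pixel_hand_value():
    """Two pixels, two classes, target (1,0) and (0,1); prediction rows
    (0.8, 0.2) and (0.4, 0.6): 1 - 2*1.4 / (2 + 1.2)."""
    target = np.array([[[1.0, 0.0]], [[0.0, 1.0]]]).reshape(1, 2, 1, 2)
    probs = np.array([[[0.8, 0.4]], [[0.2, 0.6]]]).reshape(1, 2, 1, 2)
    loss = soft_dice_loss(target, Tensor(probs)).data
    expected = 1 - 2 * (0.8 + 0.6) / (2 + 0.8**2 + 0.2**2 + 0.4**2 + 0.6**2)
    assert loss == pytest.approx(expected, abs=1e-9)


def test_dice_range_property(rng):
    for _ in range(20):
        t = one_hot(rng.integers(0, 4, size=(2, 3, 3)))
        logits = Tensor(rng.normal(size=(2, 4, 3, 3)))
        loss = soft_dice_loss(t, temperature_softmax(logits, 1.5)).data
        assert 0.0 <= loss <= 1.0


def test_dice_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        soft_dice_loss(np.zeros((1, 4, 2, 2)), Tensor(np.zeros((1, 4, 3, 3))))


def test_cross_entropy_confident_correct_is_small(rng):
    mask = rng.integers(0, 4, size=(1, 3, 3))
    t = one_hot(mask)
    logits = Tensor(1000.0 * t)
    loss = temperature_cross_entropy(t, logits, 1.0).data
    assert loss == pytest.approx(0.0, abs=1e-6)


def test_cross_entropy_uniform_is_log_classes(rng):
    t = one_hot(rng.integers(0, 4, size=(2, 3, 3)))
    loss = temperature_cross_entropy(t, Tensor(np.zeros((2, 4, 3, 3))), 1.5).data
    assert loss == pytest.approx(np.log(4), abs=1e-9)


def test_cross_entropy_matches_loop_oracle(rng):
    tau = 1.5
    mask = rng.integers(0, 4, size=(2, 3, 3))
    t = one_hot(mask)
    logits = rng.normal(size=(2, 4, 3, 3))
    loss = temperature_cross_entropy(t, Tensor(logits), tau).data
    total, count = 0.0, 0
    for n in range(2):
        for r in range(3):
            for c in range(3):
                z = logits[n, :, r, c] / tau
                p = np.exp(z - z.max())
                p /= p.sum()
                total += -np.log(p[mask[n, r, c]] + 1e-12)
                count += 1
    assert loss == pytest.approx(total / count, abs=1e-6)


def test_total_loss_degenerate_weights_skip_components(monkeypatch, rng):
    """beta1 = 1 must not evaluate the cross-entropy at all."""
    import tomaformer.losses as losses_mod
    calls = {"ce": 0, "dice": 0}
    real_ce = losses_mod.temperature_cross_entropy
    real_dice = losses_mod.soft_dice_loss
    monkeypatch.setattr(losses_mod, "temperature_cross_entropy",
                        lambda *a, **k: calls.__setitem__("ce", calls["ce"] + 1)
                        or real_ce(*a, **k))
    monkeypatch.setattr(losses_mod, "soft_dice_loss",
                        lambda *a, **k: calls.__setitem__("dice", calls["dice"] + 1)
                        or real_dice(*a, **k))
    t = one_hot(rng.integers(0, 4, size=(1, 2, 2)))
    logits = Tensor(rng.normal(size=(1, 4, 2, 2)))
    l_t, l_s1, l_s2 = losses_mod.total_loss(t, logits, LossConfig(beta1=1.0, beta2=0.0))
    assert calls == {"ce": 0, "dice": 1}
    assert l_s2.data == 0.0
    assert l_t.data == pytest.approx(l_s1.data)


def test_total_loss_is_weighted_sum(rng):
    t = one_hot(rng.integers(0, 4, size=(1, 3, 3)))
    logits = Tensor(rng.normal(size=(1, 4, 3, 3)))
    cfg = LossConfig(beta1=0.7, beta2=0.3, tau=2.0)
    l_t, l_s1, l_s2 = total_loss(t, logits, cfg)
    assert l_t.data == pytest.approx(0.7 * l_s1.data + 0.3 * l_s2.data, abs=1e-12)
    probs = temperature_softmax(Tensor(logits.data), 2.0)
    assert l_s1.data == pytest.approx(soft_dice_loss(t, probs).data)
    assert l_s2.data == pytest.approx(
        temperature_cross_entropy(t, Tensor(logits.data), 2.0).data)


@pytest.mark.parametrize("b1,b2", [(0.5, 0.4), (1.1, -0.1), (-0.2, 1.2)])
def test_weights_must_be_convex(b1, b2):
    with pytest.raises(ValueError):
        LossConfig(beta1=b1, beta2=b2)


def test_higher_temperature_softens_confident_cross_entropy(rng):
    """For a prediction that is right everywhere, raising tau moves the
    softened probabilities toward uniform and the loss increases."""
    mask = rng.integers(0, 4, size=(1, 4, 4))
    t = one_hot(mask)
    logits = Tensor(3.0 * t + rng.normal(0, 0.1, size=t.shape))
    losses = [temperature_cross_entropy(t, logits, tau).data
              for tau in (0.5, 1.0, 2.0, 4.0)]
    assert all(a < b for a, b in zip(losses, losses[1:]))


def test_total_loss_gradient_matches_finite_differences(rng):
    t = one_hot(rng.integers(0, 4, size=(1, 3, 3)))
    logits = Tensor(rng.normal(size=(1, 4, 3, 3)), requires_grad=True)
    cfg = LossConfig()
    l_t, _, _ = total_loss(t, logits, cfg)
    l_t.backward()

    def f():
        return total_loss(t, Tensor(logits.data), cfg)[0].item()

    expected = numeric_gradient(f, logits.data)
    np.testing.assert_allclose(logits.grad, expected, atol=1e-6, rtol=1e-4)
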