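"""Loss formulas against hand evaluations and brute-force loop oracles."""

import math

import numpy as np
import pytest

from cardseg.losses import (
    LossWeights, PredictionPyramid, supervised_loss, total_loss,
    uncertainty_maps, unsup_loss, weighted_cross_entropy, weighted_dice,
)


def _random_pyramid(rng, n_scales=2, shape=(2, 2, 2), n_classes=2):
    scales = []
    for _ in range(n_scales):
        logits = rng.standard_normal((n_classes,) + shape)
        p = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)
        scales.append(p)
    return PredictionPyramid(scales)


# ----------------------------------------------------------------------
# weighted cross-entropy
# ----------------------------------------------------------------------

def test_wce_two_voxel_hand_value():
    """w = (1, 3), true-class probabilities (0.5, 0.25):
    (1·ln2 + 3·ln4) / 4."""
    p = np.array([[[[0.5]], [[0.75]]], [[[0.5]], [[0.25]]]])  # (C=2, 2,1,1)
    y = np.array([[[1]], [[1]]])
    w = np.array([[[1.0]], [[3.0]]])
    expected = (1 * math.log(2) + 3 * math.log(4)) / 4
    assert float(weighted_cross_entropy(p, y, w)) == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(1.2130, abs=1e-4)


def test_wce_perfect_prediction_is_zero(rng):
    y = rng.integers(0, 2, (3, 3, 3))
    p = np.eye(2)[y].transpose(3, 0, 1, 2)
    assert float(weighted_cross_entropy(p, y, np.ones(y.shape))) == pytest.approx(0.0, abs=1e-6)


def test_wce_uniform_weights_equal_mean_ce(rng):
    p_fg = rng.uniform(0.1, 0.9, (3, 4, 5))
    p = np.stack([1 - p_fg, p_fg])
    y = rng.integers(0, 2, (3, 4, 5))
    w = np.full(y.shape, 2.7)
    mean_ce = -np.mean(np.log(np.where(y == 1, p_fg, 1 - p_fg)))
    assert float(weighted_cross_entropy(p, y, w)) == pytest.approx(mean_ce, abs=1e-9)


def test_wce_rejects_all_zero_weights(rng):
    p = np.full((2, 2, 2, 2), 0.5)
    y = np.zeros((2, 2, 2), int)
    with pytest.raises(ValueError, match="weight"):
        weighted_cross_entropy(p, y, np.zeros((2, 2, 2)))


# ----------------------------------------------------------------------
# weighted dice
# ----------------------------------------------------------------------

def test_wdice_two_voxel_hand_value():
    """w = (1, 1), y = (1, 0), p = (0.5, 0.5):
    1 − 2·0.5 / (0.25 + 1 + 0.25) = 1/3."""
    p_fg = np.array([[[0.5]], [[0.5]]])
    y = np.array([[[1]], [[0]]])
    w = np.ones((2, 1, 1))
    assert float(weighted_dice(p_fg, y, w)) == pytest.approx(1.0 / 3.0, abs=1e-9)


def test_wdice_extremes(rng):
    y = (rng.random((3, 3, 3)) > 0.5).astype(int)
    w = rng.uniform(0.5, 1.0, y.shape)
    assert float(weighted_dice(y.astype(float), y, w)) == pytest.approx(0.0, abs=1e-9)
    assert float(weighted_dice(np.zeros_like(y, dtype=float), y, w)) == pytest.approx(1.0, abs=1e-9)


def test_wdice_empty_everything_warns_and_returns_zero():
    y = np.zeros((2, 2, 2), int)
    with pytest.warns(UserWarning, match="dice"):
        v = weighted_dice(np.zeros((2, 2, 2)), y, np.ones((2, 2, 2)))
    assert float(v) == 0.0


# ----------------------------------------------------------------------
# combined supervised loss
# ----------------------------------------------------------------------

def test_supervised_loss_is_mean_of_components(rng):
    pyr = _random_pyramid(rng, n_scales=3, shape=(2, 2, 2))
    y = rng.integers(0, 2, (2, 2, 2))
    w = rng.uniform(0.2, 1.0, (2, 2, 2))
    ce = float(weighted_cross_entropy(pyr.p_scales[0].data, y, w))
    dice = float(weighted_dice(pyr.p_scales[0].data, y, w))
    assert float(supervised_loss(pyr, y, w)) == pytest.approx(0.5 * (ce + dice), abs=1e-9)


def test_supervised_loss_invariant_under_weight_rescaling(rng):
    pyr = _random_pyramid(rng)
    y = rng.integers(0, 2, (2, 2, 2))
    w = rng.uniform(0.2, 1.0, (2, 2, 2))
    a = float(supervised_loss(pyr, y, w))
    b = float(supervised_loss(pyr, y, 37.0 * w))
    assert a == pytest.approx(b, abs=1e-9)


# ----------------------------------------------------------------------
# uncertainty + consistency
# ----------------------------------------------------------------------

def test_uncertainty_zero_for_identical_scales(rng):
    p = _random_pyramid(rng, n_scales=1).p_scales[0].data
    pyr = PredictionPyramid([p, p.copy(), p.copy()])
    unc = uncertainty_maps(pyr)
    for d in unc.d_scales:
        np.testing.assert_allclose(d.data, 0.0, atol=1e-12)
    assert float(unsup_loss(pyr)) == pytest.approx(0.0, abs=1e-12)


def test_uncertainty_two_class_hand_value():
    """Voxel with p_s = (1, 0) against p_c = (0.5, 0.5): KL = ln 2."""
    ps = np.array([1.0, 0.0]).reshape(2, 1, 1, 1)
    other = np.array([0.0, 1.0]).reshape(2, 1, 1, 1)
    pyr = PredictionPyramid([ps, other])  # average is (0.5, 0.5)
    unc = uncertainty_maps(pyr, eps=1e-12)
    assert float(unc.d_scales[0].data[0, 0, 0]) == pytest.approx(math.log(2), abs=1e-6)


def test_uncertainty_nonnegative_on_random_pyramids(rng):
    for _ in range(5):
        pyr = _random_pyramid(rng, n_scales=4, shape=(3, 2, 2))
        for d in uncertainty_maps(pyr).d_scales:
            assert (d.data >= 0).all()


def test_unsup_loss_positive_when_scales_differ(rng):
    pyr = _random_pyramid(rng, n_scales=2)
    assert float(unsup_loss(pyr)) > 0


def test_unsup_loss_matches_scalar_loop_oracle(rng):
    """Brute-force double loop over scales and voxels, with w = exp(−D)."""
    pyr = _random_pyramid(rng, n_scales=2, shape=(2, 2, 2))
    eps = 1e-7
    S = 2
    p = [s.data for s in pyr.p_scales]
    pc = sum(p) / S
    total = 0.0
    for s in range(S):
        num = den = 0.0
        d_sq_sum = 0.0
        for v in np.ndindex((2, 2, 2)):
            d_v = 0.0
            sq = 0.0
            for j in range(2):
                psj = max(p[s][(j,) + v], eps)
                pcj = max(pc[(j,) + v], eps)
                d_v += psj * math.log(psj / pcj)
            d_v = max(d_v, 0.0)
            for j in range(2):
                sq += (p[s][(j,) + v] - pc[(j,) + v]) ** 2
            w_v = math.exp(-d_v)
            num += sq * w_v
            den += w_v
            d_sq_sum += d_v ** 2
        total += num / den + d_sq_sum / 8.0
    assert float(unsup_loss(pyr)) == pytest.approx(total / S, abs=1e-9)


# ----------------------------------------------------------------------
# ramp and total
# ----------------------------------------------------------------------

def test_lambda_ramp_shapes():
    lw = LossWeights(lambda_unsup=0.2, rampup_length=100, rampup_shape="gaussian")
    assert lw.lambda_at(0) <= 0.01 * 0.2  # exp(−5) of the peak: near zero
    assert lw.lambda_at(100) == pytest.approx(0.2)
    assert lw.lambda_at(500) == pytest.approx(0.2)
    # mid-ramp follows exp(−5(1 − t/T)²)
    assert lw.lambda_at(50) == pytest.approx(0.2 * math.exp(-5 * 0.25), rel=1e-12)
    values = [lw.lambda_at(t) for t in range(0, 101, 5)]
    assert all(b >= a for a, b in zip(values, values[1:]))

    linear = LossWeights(lambda_unsup=0.2, rampup_length=100, rampup_shape="linear")
    assert linear.lambda_at(25) == pytest.approx(0.05)
    const = LossWeights(lambda_unsup=0.2, rampup_shape="constant")
    assert const.lambda_at(0) == pytest.approx(0.2)


def test_total_loss_combination():
    lw = LossWeights(lambda_unsup=0.5, rampup_length=10)
    assert total_loss(1.0, 2.0, 4.0, t=10, lw=lw) == pytest.approx(1 + 2 + 0.5 * 4)
    assert total_loss(1.0, 2.0, 4.0, t=0, lw=lw) == pytest.approx(
        3.0 + 4 * 0.5 * math.exp(-5.0), rel=1e-9)


# ----------------------------------------------------------------------
# differentiability
# ----------------------------------------------------------------------

def test_losses_pass_finite_difference_gradient_check(rng):
    """All losses are differentiable wrt probabilities away from the
    ε floor; central differences agree at 1e-4 on 2³-voxel toys."""
    from cardseg.nn import Tensor

    y = rng.integers(0, 2, (2, 2, 2))
    w = rng.uniform(0.3, 1.0, (2, 2, 2))
    logits = rng.standard_normal((2, 2, 2, 2))
    p0 = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)

    def check(make_loss, x):
        loss = make_loss()
        loss.backward()
        analytic = x.grad.copy()
        numeric = np.zeros_like(x.data)
        eps = 1e-6
        it = np.nditer(x.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = x.data[i]
            x.data[i] = orig + eps
            hi = float(make_loss().data)
            x.data[i] = orig - eps
            lo = float(make_loss().data)
            x.data[i] = orig
            numeric[i] = (hi - lo) / (2 * eps)
        np.testing.assert_allclose(analytic, numeric, atol=1e-4)

    x1 = Tensor(p0.copy(), requires_grad=True)
    check(lambda: weighted_cross_entropy(x1, y, w), x1)
    x2 = Tensor(p0.copy(), requires_grad=True)
    check(lambda: weighted_dice(x2, y, w), x2)
    x3 = Tensor(p0.copy(), requires_grad=True)
    other = _random_pyramid(rng).p_scales[0].data
    check(lambda: unsup_loss(PredictionPyramid([x3, other])), x3)
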