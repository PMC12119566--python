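"""CBAP-VNet: attention blocks, variants, shapes, gradients, equivariance."""

import numpy as np
import pytest

from cardseg import nn
from cardseg.losses import supervised_loss, unsup_loss
from cardseg.network import (
    CBAM, AdaptiveChannelAttention, CBAPVNet, NetworkConfig, make_variant,
)

TINY = dict(base_channels=2, num_levels=2, pyramid_scales=2,
            cbam_positions=("down1", "down2"))


def tiny_config(**kw):
    merged = {**TINY, **kw}
    cfg = NetworkConfig(**merged)
    cfg.validate()
    return cfg


# ----------------------------------------------------------------------
# attention blocks
# ----------------------------------------------------------------------

def test_adaptive_channel_attention_zero_input():
    """Zero input: the pooled descriptor is 0, the sigmoid gate is 0.5,
    and the gated output is still exactly zero."""
    block = AdaptiveChannelAttention()
    out = block(np.zeros((1, 3, 4, 4, 4), np.float32))
    np.testing.assert_array_equal(out.data, 0.0)


def test_adaptive_channel_attention_constant_closed_form():
    for c in (-1.2, 0.3, 2.0):
        x = np.full((1, 1, 4, 4, 4), c, dtype=np.float32)
        out = AdaptiveChannelAttention()(x)
        expected = c / (1.0 + np.exp(-c))
        np.testing.assert_allclose(out.data, expected, rtol=1e-5)


def test_adaptive_channel_attention_is_contraction(rng):
    x = rng.standard_normal((2, 3, 4, 4, 4)).astype(np.float32)
    out = AdaptiveChannelAttention()(x)
    assert (np.abs(out.data) <= np.abs(x) + 1e-7).all()


def test_cbam_zero_input_and_shape(rng):
    block = CBAM(4, reduction_ratio=2, spatial_kernel=3, rng=rng)
    np.testing.assert_array_equal(block(np.zeros((1, 4, 4, 4, 4), np.float32)).data, 0.0)
    x = rng.standard_normal((2, 4, 8, 8, 8)).astype(np.float32)
    assert block(x).shape == x.shape


def test_cbam_with_saturated_gates_is_identity(rng):
    """Forcing both sigmoid pre-activations far positive makes each gate
    1, reducing the block to the identity."""
    block = CBAM(4, reduction_ratio=2, spatial_kernel=3, rng=rng)
    block.mlp2.weight.data[:] = 0.0
    block.mlp2.bias.data[:] = 50.0
    block.spatial.weight.data[:] = 0.0
    block.spatial.bias.data[:] = 100.0
    x = rng.standard_normal((1, 4, 6, 6, 6)).astype(np.float32)
    np.testing.assert_allclose(block(x).data, x, rtol=1e-5, atol=1e-6)


def test_cbam_indivisible_channels_rejected(rng):
    with pytest.raises(ValueError, match="divisible"):
        CBAM(6, reduction_ratio=4, spatial_kernel=3, rng=rng)


# ----------------------------------------------------------------------
# variants
# ----------------------------------------------------------------------

def test_variant_placements():
    v1 = make_variant(1)
    assert v1.cbam_positions == ("down1", "down2", "down3", "down4")
    assert not v1.input_attention
    v2 = make_variant(2)
    assert v2.cbam_positions == ("down1", "down2", "down3")
    assert v2.input_attention
    v3 = make_variant(3)
    assert v3.cbam_positions == ("down1", "down2", "down3", "down4")
    assert v3.input_attention
    v4 = make_variant(4)
    assert v4.cbam_positions == ("up1", "up2", "up3", "up4")
    assert v4.input_attention
    v5 = make_variant(5)
    assert v5.cbam_positions == ()
    assert not v5.input_attention
    with pytest.raises(ValueError):
        make_variant(6)


# ----------------------------------------------------------------------
# forward contract
# ----------------------------------------------------------------------

def test_forward_produces_normalized_pyramid(rng):
    net = CBAPVNet(tiny_config(), seed=0)
    x = rng.standard_normal((1, 1, 8, 8, 8)).astype(np.float32)
    pyr = net(x)
    assert pyr.num_scales == 2
    for p in pyr.p_scales:
        assert p.shape == (1, 2, 8, 8, 8)
        np.testing.assert_allclose(p.data.sum(axis=1), 1.0, atol=1e-5)
    np.testing.assert_allclose(
        pyr.p_avg.data, (pyr.p_scales[0].data + pyr.p_scales[1].data) / 2, atol=1e-7)


def test_forward_no_cross_batch_leakage(rng):
    net = CBAPVNet(tiny_config(), seed=0)
    one = rng.standard_normal((1, 1, 8, 8, 8)).astype(np.float32)
    duped = np.concatenate([one, one])
    pyr = net(duped)
    np.testing.assert_array_equal(pyr.p_scales[0].data[0], pyr.p_scales[0].data[1])


def test_forward_deterministic(rng):
    x = rng.standard_normal((1, 1, 8, 8, 8)).astype(np.float32)
    a = CBAPVNet(tiny_config(), seed=3)(x).p_scales[0].data
    b = CBAPVNet(tiny_config(), seed=3)(x).p_scales[0].data
    np.testing.assert_array_equal(a, b)


def test_indivisible_input_names_axis():
    net = CBAPVNet(tiny_config(), seed=0)
    with pytest.raises(ValueError, match="axis y"):
        net(np.zeros((1, 1, 8, 6, 8), np.float32))


def test_parameter_count_matches_hand_tally():
    """Plain 2-level VNet, base 2: enumerate every layer's parameter
    shapes independently and sum."""
    cfg = NetworkConfig(base_channels=2, num_levels=2, pyramid_scales=2,
                        cbam_positions=(), input_attention=False)
    net = CBAPVNet(cfg, seed=0)

    def conv(cin, cout, k):
        return cout * cin * k ** 3 + cout

    def stage(cin, cout, n):  # n convs + IN + PReLU each, plus projection
        total = conv(cin, cout, 3) + 2 * cout + cout
        total += (n - 1) * (conv(cout, cout, 3) + 2 * cout + cout)
        if cin != cout:
            total += conv(cin, cout, 1)
        return total

    expected = stage(1, 2, 1)                      # stem
    expected += conv(2, 4, 2) + 2 * 4 + 4 + stage(4, 4, 2)    # down1
    expected += conv(4, 8, 2) + 2 * 8 + 8 + stage(8, 8, 3)    # down2
    expected += conv(8, 4, 2) + 2 * 4 + 4 + stage(8, 4, 2)    # up1 (concat in)
    expected += conv(4, 2, 2) + 2 * 2 + 2 + stage(4, 2, 1)    # up2 (concat in)
    expected += conv(2, 2, 1) + conv(4, 2, 1)                  # heads at levels 0, 1
    assert net.num_parameters() == expected


@pytest.mark.parametrize("method_id", [1, 2, 3, 4, 5])
def test_gradient_reaches_every_parameter(method_id, rng):
    """No dead branches: with the full loss, every trainable parameter of
    every placement variant receives a non-zero gradient."""
    cfg = make_variant(method_id, base_channels=2)
    net = CBAPVNet(cfg, seed=1)
    # 32 voxels per axis keeps the 4-level bottleneck at 2 voxels, where
    # instance norm is still informative
    x = rng.standard_normal((1, 1, 32, 32, 32)).astype(np.float32)
    y = (rng.random((32, 32, 32)) > 0.5).astype(np.uint8)
    w = np.ones((32, 32, 32), np.float32)
    pyr = net(x)
    loss = supervised_loss(pyr.item(0), y, w) + unsup_loss(pyr.item(0))
    loss.backward()
    dead = [name for name, p in net.named_parameters()
            if p.grad is None or not np.any(p.grad != 0)]
    assert dead == []


def test_translation_equivariance_of_coarse_features():
    """Translating a compactly supported input by one full downsampling
    period translates the coarsest encoder features by one voxel, away
    from the borders."""
    cfg = tiny_config()
    net = CBAPVNet(cfg, seed=0)
    period = 2 ** cfg.num_levels

    rng = np.random.default_rng(0)
    x = np.zeros((1, 1, 64, 8, 8), np.float32)
    x[0, 0, 24:28, 2:6, 2:6] = rng.standard_normal((4, 4, 4))
    x_shift = np.roll(x, period, axis=2)

    def encode(inp):
        f = net.stem(nn.astensor(inp))
        f = net.down1(f)
        return net.down2(f).data  # (1, C, 16, 2, 2)

    f0 = encode(x)
    f1 = encode(x_shift)
    # interior coarse cells only; tolerance covers float32 noise amplified
    # by instance norm on the near-constant background
    np.testing.assert_allclose(f1[:, :, 6:10], f0[:, :, 5:9], atol=2e-2)
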