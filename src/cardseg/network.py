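"""CBAP-VNet: a VNet encoder-decoder with CBAM attention on the
downsampling blocks, an adaptive channel attention block at the input, and
multi-scale prediction heads feeding the uncertainty-rectified consistency
loss.

Backbone: residual convolution stages, strided-convolution downsampling,
transposed-convolution upsampling, skip concatenations; channel widths
double per level from ``base_channels``.  The pyramid heads are 1-voxel
classifiers on the decoder stages (full, 1/2, 1/4, ... resolution), each
trilinearly upsampled to full resolution and softmax-normalized.

``make_variant`` reproduces the five attention-placement ablation variants:
1 CBAM on all four down stages; 2 input attention + CBAM on three down
stages; 3 input attention + CBAM on all four down stages (the proposed
CBAP-VNet); 4 input attention + CBAM on the four up stages; 5 plain VNet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import functional as F
from .losses import PredictionPyramid

__all__ = [
    "NetworkConfig", "CBAPVNet", "AdaptiveChannelAttention", "CBAM",
    "make_variant",
]


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    num_classes: int = 2
    base_channels: int = 16
    num_levels: int = 4
    cbam_positions: tuple[str, ...] = ("down1", "down2", "down3", "down4")
    input_attention: bool = True
    reduction_ratio: int = 16
    spatial_kernel: int = 7
    pyramid_scales: int = 4

    def validate(self) -> None:
        if self.num_levels < 1:
            raise ValueError("num_levels must be >= 1")
        if self.base_channels < 1 or self.num_classes < 2:
            raise ValueError("base_channels >= 1 and num_classes >= 2 required")
        valid = {f"down{i}" for i in range(1, self.num_levels + 1)}
        valid |= {f"up{i}" for i in range(1, self.num_levels + 1)}
        bad = set(self.cbam_positions) - valid
        if bad:
            raise ValueError(f"unknown CBAM positions {sorted(bad)}; valid: {sorted(valid)}")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")
        if not 1 <= self.pyramid_scales <= self.num_levels + 1:
            raise ValueError(
                f"pyramid_scales must be in [1, num_levels + 1], got {self.pyramid_scales}"
            )

    def channels(self, level: int) -> int:
        return self.base_channels * 2 ** level

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cbam_positions"] = list(d["cbam_positions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["cbam_positions"] = tuple(d.get("cbam_positions", ()))
        return cls(**d)


def make_variant(method_id: int, **overrides) -> NetworkConfig:
    """Attention-placement ablation variants 1-5 (3 is the full CBAP-VNet)."""
    placements = {
        1: (("down1", "down2", "down3", "down4"), False),
        2: (("down1", "down2", "down3"), True),
        3: (("down1", "down2", "down3", "down4"), True),
        4: (("up1", "up2", "up3", "up4"), True),
        5: ((), False),
    }
    if method_id not in placements:
        raise ValueError(f"variant id must be 1..5, got {method_id}")
    cbam, input_attention = placements[method_id]
    cfg = NetworkConfig(
        cbam_positions=cbam, input_attention=input_attention, **overrides
    )
    cfg.validate()
    return cfg


class AdaptiveChannelAttention(nn.Module):
    """Parameter-free input gating: x ⊙ sigmoid(global average pool of x).

    The pooled per-channel descriptor passes through a sigmoid and
    multiplies the original data elementwise, so the gate lies in (0, 1)
    and the block is a contraction.
    """

    def forward(self, x):
        return x * F.sigmoid(F.global_avg_pool(x))


class CBAM(nn.Module):
    """Convolutional block attention: channel attention (shared MLP over
    average- and max-pooled descriptors, summed, sigmoid) followed by
    spatial attention (convolution over the channelwise average and max
    maps, sigmoid)."""

    def __init__(self, channels: int, reduction_ratio: int, spatial_kernel: int, rng):
        super().__init__()
        r = min(reduction_ratio, channels)
        if channels % r != 0:
            raise ValueError(
                f"CBAM channels ({channels}) not divisible by reduction ratio ({r})"
            )
        hidden = max(1, channels // r)
        self.mlp1 = nn.Conv3d(channels, hidden, 1, rng)
        self.mlp2 = nn.Conv3d(hidden, channels, 1, rng)
        self.spatial = nn.Conv3d(2, 1, spatial_kernel, rng)

    @staticmethod
    def _lrelu(x):
        # leaky slope keeps the narrow reduction bottleneck from going dead
        pos = F.relu(x)
        return pos + 0.01 * (x - pos)

    def _mlp(self, descriptor):
        return self.mlp2(self._lrelu(self.mlp1(descriptor)))

    def forward(self, x):
        avg = self._mlp(F.global_avg_pool(x))
        mx = self._mlp(F.global_max_pool(x))
        x = x * F.sigmoid(avg + mx)
        s_avg = F.mean(x, axis=1, keepdims=True)
        s_max = F.amax(x, axis=1, keepdims=True)
        gate = F.sigmoid(self.spatial(F.concat([s_avg, s_max], axis=1)))
        return x * gate


class ResidualStage(nn.Module):
    """``n_convs`` 3x3x3 conv + instance norm + PReLU, with a residual
    connection (1x1x1 projection when channel counts differ)."""

    def __init__(self, in_ch: int, out_ch: int, n_convs: int, rng):
        super().__init__()
        layers = []
        ch = in_ch
        for _ in range(n_convs):
            layers += [nn.Conv3d(ch, out_ch, 3, rng), nn.InstanceNorm3d(out_ch), nn.PReLU(out_ch)]
            ch = out_ch
        self.body = nn.Sequential(*layers)
        self.project = None if in_ch == out_ch else nn.Conv3d(in_ch, out_ch, 1, rng)

    def forward(self, x):
        skip = x if self.project is None else self.project(x)
        return self.body(x) + skip


class _DownBlock(nn.Module):
    def __init__(self, in_ch, out_ch, n_convs, rng):
        super().__init__()
        self.down = nn.DownConv2(in_ch, out_ch, rng)
        self.norm = nn.InstanceNorm3d(out_ch)
        self.act = nn.PReLU(out_ch)
        self.stage = ResidualStage(out_ch, out_ch, n_convs, rng)

    def forward(self, x):
        return self.stage(self.act(self.norm(self.down(x))))


class _UpBlock(nn.Module):
    def __init__(self, in_ch, out_ch, n_convs, rng):
        super().__init__()
        self.up = nn.UpConv2(in_ch, out_ch, rng)
        self.norm = nn.InstanceNorm3d(out_ch)
        self.act = nn.PReLU(out_ch)
        self.stage = ResidualStage(2 * out_ch, out_ch, n_convs, rng)

    def forward(self, x, skip):
        x = self.act(self.norm(self.up(x)))
        return self.stage(F.concat([x, skip], axis=1))


class CBAPVNet(nn.Module):
    """The segmentation network; ``forward`` returns a
    :class:`~cardseg.losses.PredictionPyramid` of S class-probability
    grids at full resolution plus, implicitly, their average."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        L, B = config.num_levels, config.base_channels

        if config.input_attention:
            self.input_attention = AdaptiveChannelAttention()
        self.stem = ResidualStage(config.in_channels, B, 1, rng)

        for l in range(1, L + 1):
            block = _DownBlock(config.channels(l - 1), config.channels(l), min(l + 1, 3), rng)
            setattr(self, f"down{l}", block)
            if f"down{l}" in config.cbam_positions:
                setattr(
                    self, f"cbam_down{l}",
                    CBAM(config.channels(l), config.reduction_ratio, config.spatial_kernel, rng),
                )
        for i, l in enumerate(range(L - 1, -1, -1), start=1):
            # up1 acts on the deepest feature; upL produces the full-res one
            block = _UpBlock(config.channels(l + 1), config.channels(l), min(l + 1, 3), rng)
            setattr(self, f"up{i}", block)
            if f"up{i}" in config.cbam_positions:
                setattr(
                    self, f"cbam_up{i}",
                    CBAM(config.channels(l), config.reduction_ratio, config.spatial_kernel, rng),
                )
        for s in range(config.pyramid_scales):
            ch = config.channels(min(s, L))
            setattr(self, f"head{s}", nn.Conv3d(ch, config.num_classes, 1, rng))

    # ------------------------------------------------------------------
    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def _check_shape(self, shape):
        period = 2 ** self.config.num_levels
        names = "xyz"
        for axis, n in enumerate(shape):
            if n % period:
                raise ValueError(
                    f"input axis {names[axis]} has extent {n}, not divisible by "
                    f"2^num_levels = {period}"
                )

    def forward(self, x) -> PredictionPyramid:
        """``x``: (N, in_channels, X, Y, Z) array or tensor."""
        x = nn.astensor(x)
        if x.ndim != 5:
            raise ValueError(f"expected 5D input (N, C, X, Y, Z), got shape {x.shape}")
        self._check_shape(x.shape[2:])
        cfg = self.config
        L = cfg.num_levels

        if cfg.input_attention:
            x = self.input_attention(x)
        feats = [self.stem(x)]
        for l in range(1, L + 1):
            f = getattr(self, f"down{l}")(feats[-1])
            if f"down{l}" in cfg.cbam_positions:
                f = getattr(self, f"cbam_down{l}")(f)
            feats.append(f)

        # decoder features indexed by level: dec[l] has channels(l) at 1/2^l res
        dec = {L: feats[L]}
        for i, l in enumerate(range(L - 1, -1, -1), start=1):
            f = getattr(self, f"up{i}")(dec[l + 1], feats[l])
            if f"up{i}" in cfg.cbam_positions:
                f = getattr(self, f"cbam_up{i}")(f)
            dec[l] = f

        scales = []
        for s in range(cfg.pyramid_scales):
            logits = getattr(self, f"head{s}")(dec[min(s, L)])
            logits = F.upsample_trilinear(logits, 2 ** min(s, L))
            scales.append(F.softmax(logits, axis=1))
        return PredictionPyramid(scales)
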