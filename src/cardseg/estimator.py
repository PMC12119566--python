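"""Scikit-learn-style estimator facade over the mean-teacher trainer.

``MeanTeacherSegmenter`` follows the sklearn semi-supervised convention:
``fit(X, y)`` takes a sequence of 3D volumes and a sequence of label maps
in which ``None`` marks an unlabeled volume.  It composes with sklearn
model-selection utilities through ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import Volume
from .losses import LossWeights
from .metrics import overlap_metrics
from .network import CBAPVNet, NetworkConfig, make_variant
from .nn import SGD
from .trainer import (
    TrainConfig, TrainState, items_from_arrays, predict_volume, training_step,
)

__all__ = ["MeanTeacherSegmenter"]


class MeanTeacherSegmenter(BaseEstimator):
    """Semi-supervised 3D segmentation with a mean-teacher CBAP-VNet.

    Parameters mirror the library's training, network, supervision,
    augmentation and loss configuration.  ``variant`` selects the
    attention-placement ablation (1-5; 3 is the full CBAP-VNet) when
    ``num_levels`` is 4; otherwise ``cbam`` ("down", "up" or "none") and
    ``input_attention`` place the attention blocks explicitly.

    Attributes (after ``fit``)
    --------------------------
    student_ : CBAPVNet — the SGD-trained network.
    teacher_ : CBAPVNet — its exponential moving average (used to predict).
    history_ : DataFrame — per-iteration loss terms.
    n_iter_ : int — number of optimization steps run.
    """

    def __init__(
        self,
        *,
        variant: int | None = None,
        base_channels: int = 4,
        num_levels: int = 2,
        pyramid_scales: int = 2,
        cbam: str = "down",
        input_attention: bool = True,
        reduction_ratio: int = 16,
        spatial_kernel: int = 7,
        max_iterations: int = 300,
        lr: float = 0.01,
        momentum: float = 0.9,
        weight_decay: float = 1e-4,
        ema_decay: float = 0.95,
        noise_sigma: float = 0.1,
        patch_shape: tuple = (16, 16, 16),
        stride: tuple | None = None,
        cutmix_enabled: bool = True,
        cutmix_alpha: float = 1.0,
        cutmix_prob: float = 0.5,
        decay_weight: float = 0.95,
        combine_rule: str = "product",
        source_index="middle",
        band_width: int = 1,
        lambda_unsup: float = 0.1,
        rampup_length: int = 40,
        rampup_shape: str = "gaussian",
        ce_dice_ratio: float = 0.5,
        predict_with_teacher: bool = True,
        seed: int = 0,
    ):
        self.variant = variant
        self.base_channels = base_channels
        self.num_levels = num_levels
        self.pyramid_scales = pyramid_scales
        self.cbam = cbam
        self.input_attention = input_attention
        self.reduction_ratio = reduction_ratio
        self.spatial_kernel = spatial_kernel
        self.max_iterations = max_iterations
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.ema_decay = ema_decay
        self.noise_sigma = noise_sigma
        self.patch_shape = patch_shape
        self.stride = stride
        self.cutmix_enabled = cutmix_enabled
        self.cutmix_alpha = cutmix_alpha
        self.cutmix_prob = cutmix_prob
        self.decay_weight = decay_weight
        self.combine_rule = combine_rule
        self.source_index = source_index
        self.band_width = band_width
        self.lambda_unsup = lambda_unsup
        self.rampup_length = rampup_length
        self.rampup_shape = rampup_shape
        self.ce_dice_ratio = ce_dice_ratio
        self.predict_with_teacher = predict_with_teacher
        self.seed = seed

    # ------------------------------------------------------------------
    def _network_config(self) -> NetworkConfig:
        if self.variant is not None:
            return make_variant(
                self.variant,
                base_channels=self.base_channels,
                num_levels=self.num_levels,
                pyramid_scales=self.pyramid_scales,
                reduction_ratio=self.reduction_ratio,
                spatial_kernel=self.spatial_kernel,
            )
        if self.cbam == "down":
            positions = tuple(f"down{i}" for i in range(1, self.num_levels + 1))
        elif self.cbam == "up":
            positions = tuple(f"up{i}" for i in range(1, self.num_levels + 1))
        elif self.cbam == "none":
            positions = ()
        else:
            raise ValueError(f"cbam must be 'down', 'up' or 'none', got {self.cbam!r}")
        cfg = NetworkConfig(
            base_channels=self.base_channels,
            num_levels=self.num_levels,
            pyramid_scales=self.pyramid_scales,
            cbam_positions=positions,
            input_attention=self.input_attention,
            reduction_ratio=self.reduction_ratio,
            spatial_kernel=self.spatial_kernel,
        )
        cfg.validate()
        return cfg

    def _train_config(self, semi_enabled: bool) -> TrainConfig:
        return TrainConfig(
            max_iterations=self.max_iterations,
            lr=self.lr,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            ema_decay=self.ema_decay,
            noise_sigma=self.noise_sigma,
            patch_shape=tuple(self.patch_shape),
            stride=None if self.stride is None else tuple(self.stride),
            seed=self.seed,
            semi_enabled=semi_enabled,
            cutmix_enabled=self.cutmix_enabled,
            cutmix_alpha=self.cutmix_alpha,
            cutmix_prob=self.cutmix_prob,
            decay_weight=self.decay_weight,
            combine_rule=self.combine_rule,
            source_index=self.source_index,
            band_width=self.band_width,
            ce_dice_ratio=self.ce_dice_ratio,
            loss_weights=LossWeights(
                lambda_unsup=self.lambda_unsup,
                rampup_length=self.rampup_length,
                rampup_shape=self.rampup_shape,
            ),
            predict_with_teacher=self.predict_with_teacher,
        )

    # ------------------------------------------------------------------
    def fit(self, X, y):
        """Train on volumes ``X`` with labels ``y`` (None = unlabeled)."""
        if len(X) != len(y):
            raise ValueError(f"X and y lengths differ: {len(X)} vs {len(y)}")
        semi = any(lab is None for lab in y)
        cfg = self._train_config(semi_enabled=semi)
        cfg.validate()
        net_config = self._network_config()
        items = items_from_arrays(X, y, cfg)

        student = CBAPVNet(net_config, seed=cfg.seed)
        teacher = CBAPVNet(net_config, seed=cfg.seed)
        teacher.load_state_dict(student.state_dict())
        optimizer = SGD(student.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                        weight_decay=cfg.weight_decay)
        state = TrainState(student=student, teacher=teacher, optimizer=optimizer,
                           rng=np.random.default_rng(cfg.seed))
        while state.iteration < cfg.max_iterations:
            training_step(state, items, cfg)

        self.student_ = student
        self.teacher_ = teacher
        self.history_ = pd.DataFrame(state.history)
        self.n_iter_ = state.iteration
        self.net_config_ = net_config
        self.train_config_ = cfg
        return self

    def predict(self, X):
        """Segment each volume; returns a list of uint8 label arrays."""
        if not hasattr(self, "teacher_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        net = self.teacher_ if self.predict_with_teacher else self.student_
        out = []
        for vol in X:
            volume = vol if isinstance(vol, Volume) else Volume(data=np.asarray(vol))
            out.append(
                predict_volume(net, volume, tuple(self.patch_shape), self.stride).data
            )
        return out

    def score(self, X, y):
        """Mean Dice overlap (fraction in [0, 1]) against label maps ``y``."""
        preds = self.predict(X)
        dices = []
        for pred, lab in zip(preds, y):
            lab = lab.data if hasattr(lab, "data") else np.asarray(lab)
            dice, _ = overlap_metrics(pred, lab)
            dices.append(dice / 100.0)
        return float(np.mean(dices))
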