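"""The training loss system.

Total loss:  L_total = L_sup + L_semi + λ(t) · L_unsup, where

* L_sup  — weighted cross-entropy + weighted Dice against ground truth on
  labeled data, weights from the multi-view slice-confidence map;
* L_semi — the same combination against teacher pseudo-labels on unlabeled
  and mixed data;
* L_unsup — uncertainty-rectified multi-scale consistency: the prediction
  pyramid's per-scale deviation from the scale-average prediction, with
  per-voxel rectification weights exp(−D_s) built from the KL-divergence
  uncertainty maps D_s, plus an uncertainty-minimization term mean(D_s²).

All losses are differentiable (inputs may be plain arrays or autodiff
tensors) and vanish at the perfect-prediction / perfect-consistency fixed
point.  Probabilities are floored at ``eps`` inside logarithms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .nn import Tensor, astensor
from .nn import functional as F

__all__ = [
    "PredictionPyramid", "UncertaintyMap", "LossWeights",
    "weighted_cross_entropy", "weighted_dice", "supervised_loss",
    "uncertainty_maps", "unsup_loss", "total_loss",
]

EPS = 1e-7


@dataclass
class PredictionPyramid:
    """Multi-scale class-probability grids, all at full resolution.

    Each entry of ``p_scales`` has shape (..., C, X, Y, Z) — a leading
    batch axis is allowed; the class axis is always the fourth from the
    right.  ``p_avg`` is the voxelwise mean across scales.
    """

    p_scales: list

    def __post_init__(self):
        if len(self.p_scales) < 1:
            raise ValueError("pyramid needs at least one scale")
        self.p_scales = [astensor(p) for p in self.p_scales]
        shapes = {p.shape for p in self.p_scales}
        if len(shapes) != 1:
            raise ValueError(f"pyramid scales disagree in shape: {shapes}")

    @property
    def num_scales(self) -> int:
        return len(self.p_scales)

    @property
    def class_axis(self) -> int:
        return self.p_scales[0].ndim - 4

    @property
    def p_avg(self) -> Tensor:
        total = self.p_scales[0]
        for p in self.p_scales[1:]:
            total = total + p
        return total * (1.0 / len(self.p_scales))

    def item(self, n: int) -> "PredictionPyramid":
        """Select one sample from a batched pyramid."""
        return PredictionPyramid([p[n] for p in self.p_scales])


@dataclass
class UncertaintyMap:
    """Per-scale KL uncertainty grids D_0..D_{S-1}; non-negative, zero
    wherever the scale prediction equals the average prediction."""

    d_scales: list


@dataclass(frozen=True)
class LossWeights:
    """Ramped weight λ(t) of the consistency term.

    The Gaussian ramp ``exp(−5·(1 − t/T)²)`` is the standard mean-teacher
    warm-up: near zero early (≈ 0.7% of the peak at t = 0), reaching
    ``lambda_unsup`` at ``t = rampup_length`` and constant after.
    """

    lambda_unsup: float = 0.1
    rampup_length: int = 40
    rampup_shape: str = "gaussian"

    def __post_init__(self):
        if self.lambda_unsup < 0:
            raise ValueError("lambda_unsup must be >= 0")
        if self.rampup_shape not in ("gaussian", "linear", "constant"):
            raise ValueError(f"unknown rampup_shape {self.rampup_shape!r}")

    def lambda_at(self, t: int) -> float:
        T = self.rampup_length
        if self.rampup_shape == "constant" or T <= 0 or t >= T:
            return self.lambda_unsup
        frac = max(0.0, min(1.0, t / T))
        if self.rampup_shape == "linear":
            return self.lambda_unsup * frac
        return self.lambda_unsup * math.exp(-5.0 * (1.0 - frac) ** 2)


def _floor(p: Tensor, eps: float) -> Tensor:
    # differentiable floor: values below eps are clamped (zero gradient there)
    return F.relu(p - eps) + eps


def _check_weights(w: np.ndarray):
    if (w < 0).any():
        raise ValueError("weight map must be non-negative")
    if w.sum() == 0:
        raise ValueError("weight map sums to zero: nothing to supervise")


def weighted_cross_entropy(p, y, w, eps: float = EPS) -> Tensor:
    """−Σᵢ wᵢ · log pᵢ[yᵢ] / Σᵢ wᵢ over voxels i.

    ``p``: class probabilities (C, X, Y, Z); ``y``: integer labels
    (X, Y, Z); ``w``: per-voxel confidence weights.
    """
    p = astensor(p)
    y = np.asarray(y).astype(np.int64)
    w = np.asarray(w, dtype=np.float64)
    if p.shape[1:] != y.shape or y.shape != w.shape:
        raise ValueError(
            f"shape mismatch: p {p.shape}, y {y.shape}, w {w.shape}"
        )
    _check_weights(w)
    dt = p.data.dtype
    onehot = np.eye(p.shape[0], dtype=dt)[y]  # (X,Y,Z,C)
    onehot = np.moveaxis(onehot, -1, 0)
    p_true = F.sum(p * astensor(onehot), axis=0)
    nll = F.log(_floor(p_true, eps)) * astensor(w.astype(dt))
    return F.sum(nll) * (-1.0 / float(w.sum()))


def weighted_dice(p, y, w, eps: float = EPS) -> Tensor:
    """1 − 2·Σ wᵢyᵢpᵢ / Σ wᵢ(pᵢ² + yᵢ²) on the foreground channel.

    ``p`` may be the full class grid (C, X, Y, Z) — channel 1 is used —
    or the foreground probability grid directly.
    """
    p = astensor(p)
    y = np.asarray(y)
    w = np.asarray(w, dtype=np.float64)
    if p.ndim == y.ndim + 1:
        p = p[1]
    if p.shape != y.shape or y.shape != w.shape:
        raise ValueError(f"shape mismatch: p {p.shape}, y {y.shape}, w {w.shape}")
    _check_weights(w)
    dt = p.data.dtype
    yf = (y > 0).astype(dt)
    wt = astensor(w.astype(dt))
    num = F.sum(wt * astensor(yf) * p) * 2.0
    den = F.sum(wt * (p * p + astensor(yf * yf)))
    if float(den.data) == 0.0:
        warnings.warn("empty foreground and zero prediction: dice loss defined as 0")
        return astensor(0.0)
    return 1.0 - num / den


def supervised_loss(pyramid, y, w, ce_dice_ratio: float = 0.5, eps: float = EPS) -> Tensor:
    """Equal-weight combination of weighted CE and weighted Dice on the
    full-resolution prediction (the pyramid's finest scale)."""
    p = pyramid.p_scales[0] if isinstance(pyramid, PredictionPyramid) else astensor(pyramid)
    ce = weighted_cross_entropy(p, y, w, eps)
    dice = weighted_dice(p, y, w, eps)
    return ce_dice_ratio * ce + (1.0 - ce_dice_ratio) * dice


def uncertainty_maps(pyramid: PredictionPyramid, eps: float = EPS) -> UncertaintyMap:
    """KL divergence of each scale from the scale-average prediction:
    D_s[v] = Σ_j p_s^j[v] · log(p_s^j[v] / p_c^j[v])."""
    axis = pyramid.class_axis
    pc = _floor(pyramid.p_avg, eps)
    d_scales = []
    for ps in pyramid.p_scales:
        psf = _floor(ps, eps)
        kl = F.sum(psf * (F.log(psf) - F.log(pc)), axis=axis)
        d_scales.append(F.relu(kl))  # clip the tiny negatives from flooring
    return UncertaintyMap(d_scales=d_scales)


def unsup_loss(pyramid: PredictionPyramid, eps: float = EPS) -> Tensor:
    """Uncertainty-rectified consistency plus uncertainty minimization.

    (1/S)·Σ_s [ Σ_v ‖p_s − p_c‖²·w_s^v / Σ_v w_s^v ]  +  (1/S)·Σ_s mean(D_s²)

    with rectification weights w_s^v = exp(−D_s^v): voxels where a scale
    disagrees with the consensus are down-weighted in the consistency term
    but pushed toward it by the minimization term.
    """
    S = pyramid.num_scales
    axis = pyramid.class_axis
    pc = pyramid.p_avg
    unc = uncertainty_maps(pyramid, eps)
    total = astensor(0.0)
    for ps, d in zip(pyramid.p_scales, unc.d_scales):
        diff = ps - pc
        sq = F.sum(diff * diff, axis=axis)  # per-voxel squared deviation
        w = F.exp(-1.0 * d)
        rectified = F.sum(sq * w) / F.sum(w)
        minimization = F.mean(d * d)
        total = total + rectified + minimization
    return total * (1.0 / S)


def total_loss(sup, semi, unsup, t: int, lw: LossWeights):
    """L_total = L_sup + L_semi + λ(t)·L_unsup with the ramped weight."""
    return sup + semi + lw.lambda_at(t) * unsup
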