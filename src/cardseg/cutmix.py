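"""Volumetric CutMix: replace an axis-aligned box of one sample with the
corresponding box of another, mixing label maps with the same binary mask.

The mixing ratio λ ~ Beta(α, α) with α = 1 (i.e. uniform on (0, 1)) gives
the fraction of voxels kept from sample A; the cut box has volume fraction
1 − λ, with side lengths scaled by (1 − λ)^(1/3) per axis.  Label mixing
acts on hard label maps, so the mixed label remains a valid integer map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MixSample", "sample_lambda", "sample_box_mask", "cutmix", "apply_mask"]


@dataclass
class MixSample:
    """One CutMix output: mixed volume/label, the mask M (1 = keep A),
    and the realized kept-fraction ``lam``."""

    x_mix: np.ndarray
    y_mix: np.ndarray
    mask: np.ndarray
    lam: float


def sample_lambda(alpha: float, rng: np.random.Generator) -> float:
    """Draw the mixing ratio λ ∈ [0, 1] from Beta(α, α)."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return float(rng.beta(alpha, alpha))


def sample_box_mask(shape, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Binary mask that is 1 outside a single axis-aligned box, 0 inside.

    Box side lengths are ``round(shape_i * (1 - lam)**(1/3))``, placed
    uniformly at random fully inside the grid; the fraction of ones equals
    ``lam`` up to the rounding of the three side lengths.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    shape = tuple(int(s) for s in shape)
    mask = np.ones(shape, dtype=np.uint8)
    cut = (1.0 - lam) ** (1.0 / 3.0)
    sides = [min(n, int(round(n * cut))) for n in shape]
    if any(s == 0 for s in sides):
        return mask
    corner = [int(rng.integers(0, n - s + 1)) for n, s in zip(shape, sides)]
    sl = tuple(slice(c, c + s) for c, s in zip(corner, sides))
    mask[sl] = 0
    return mask


def cutmix(a, b, alpha: float, rng: np.random.Generator) -> MixSample:
    """Mix two (volume, label) pairs of identical shape.

    The recorded ``lam`` is the realized ones-fraction of the mask, not the
    drawn λ.  ``cutmix(a, b)`` with mask M equals ``cutmix(b, a)`` with
    mask 1 − M.
    """
    xa, ya = a
    xb, yb = b
    xa, ya, xb, yb = (np.asarray(v) for v in (xa, ya, xb, yb))
    if xa.shape != xb.shape or ya.shape != yb.shape or xa.shape != ya.shape:
        raise ValueError(
            f"cutmix requires matching shapes, got {xa.shape}/{ya.shape} "
            f"vs {xb.shape}/{yb.shape}"
        )
    lam = sample_lambda(alpha, rng)
    mask = sample_box_mask(xa.shape, lam, rng)
    return apply_mask(a, b, mask)


def apply_mask(a, b, mask: np.ndarray) -> MixSample:
    """Deterministic part of CutMix: blend two pairs with a given mask."""
    xa, ya = a
    xb, yb = b
    mask = np.asarray(mask)
    keep = mask.astype(bool)
    x_mix = np.where(keep, xa, xb)
    y_mix = np.where(keep, ya, yb).astype(np.asarray(ya).dtype)
    return MixSample(x_mix=x_mix, y_mix=y_mix, mask=mask, lam=float(keep.mean()))
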