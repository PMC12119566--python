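"""Multi-view slice-confidence supervision.

Voxels are weighted by the confidence of their slice relative to a source
slice in each of two views (transverse and coronal).  The source slice has
confidence 1; confidence decays exponentially with slice distance d as
``decay_weight ** d``.  The two per-view maps are fused voxelwise
(product by default: a voxel is confidently supervised only where both
views are confident).  With ``decay_weight = 1`` every weight is 1 and the
weighted losses reduce exactly to their unweighted forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SliceWeightSpec", "slice_confidence", "build_view_weightmap",
    "combine_views", "build_weightmap", "VIEW_AXES",
]

# transverse slices stack along z, coronal slices along y
VIEW_AXES = {"transverse": 2, "coronal": 1}
_COMBINE_RULES = ("product", "max", "mean")


@dataclass(frozen=True)
class SliceWeightSpec:
    """Weighting of one view.

    ``source_index`` is a slice index, "middle", or "none" (uniform weights,
    i.e. no slice supervision signal).  ``band_width`` > 1 selects a
    contiguous band of source slices centred on ``source_index``; distance
    is then measured to the nearest slice of the band.  These options cover
    the slice-position variants (edge slice / middle band / single middle /
    none) so their effect can be re-run on phantoms.
    """

    view: str = "transverse"
    source_index: int | str = "middle"
    decay_weight: float = 0.95
    band_width: int = 1

    def __post_init__(self):
        if self.view not in VIEW_AXES:
            raise ValueError(
                f"unknown view {self.view!r}; expected one of {sorted(VIEW_AXES)}"
            )
        if not 0.0 < self.decay_weight <= 1.0:
            raise ValueError(f"decay_weight must be in (0, 1], got {self.decay_weight}")
        if self.band_width < 1:
            raise ValueError("band_width must be >= 1")


def slice_confidence(d, decay_weight: float):
    """Confidence of a slice at integer distance ``d`` from the source.

    Returns 1 at d = 0 and ``decay_weight ** d`` otherwise; always in (0, 1].
    """
    d = np.asarray(d)
    if np.any(d < 0):
        raise ValueError("slice distance must be non-negative")
    if not 0.0 < decay_weight <= 1.0:
        raise ValueError(f"decay_weight must be in (0, 1], got {decay_weight}")
    out = np.where(d == 0, 1.0, np.power(float(decay_weight), d.astype(np.float64)))
    return float(out) if out.ndim == 0 else out


def build_view_weightmap(shape, spec: SliceWeightSpec) -> np.ndarray:
    """Per-voxel weights for one view: constant within each slice along the
    view axis, equal to the slice's confidence."""
    shape = tuple(int(s) for s in shape)
    axis = VIEW_AXES[spec.view]
    n = shape[axis]
    if spec.source_index == "none":
        return np.ones(shape, dtype=np.float32)
    if spec.source_index == "middle":
        src = n // 2
    else:
        src = int(spec.source_index)
        if not 0 <= src < n:
            raise ValueError(
                f"source_index {src} outside extent {n} of the {spec.view} axis"
            )
    half = (spec.band_width - 1) // 2
    lo, hi = max(0, src - half), min(n - 1, src + half)
    idx = np.arange(n)
    dist = np.maximum(0, np.maximum(lo - idx, idx - hi))
    conf = slice_confidence(dist, spec.decay_weight)
    bshape = [1, 1, 1]
    bshape[axis] = n
    return np.broadcast_to(conf.reshape(bshape), shape).astype(np.float32).copy()


def combine_views(w_a: np.ndarray, w_b: np.ndarray, rule: str = "product") -> np.ndarray:
    """Fuse two per-view weight maps voxelwise."""
    w_a, w_b = np.asarray(w_a), np.asarray(w_b)
    if w_a.shape != w_b.shape:
        raise ValueError(f"weight map shapes differ: {w_a.shape} vs {w_b.shape}")
    if rule == "product":
        return (w_a * w_b).astype(np.float32)
    if rule == "max":
        return np.maximum(w_a, w_b).astype(np.float32)
    if rule == "mean":
        return (0.5 * (w_a + w_b)).astype(np.float32)
    raise ValueError(f"unknown combine rule {rule!r}; expected one of {_COMBINE_RULES}")


def build_weightmap(
    shape,
    decay_weight: float = 0.95,
    combine_rule: str = "product",
    source_index="middle",
    band_width: int = 1,
) -> np.ndarray:
    """Two-view (transverse + coronal) weight map in one call."""
    maps = [
        build_view_weightmap(
            shape,
            SliceWeightSpec(
                view=view,
                source_index=source_index,
                decay_weight=decay_weight,
                band_width=band_width,
            ),
        )
        for view in ("transverse", "coronal")
    ]
    return combine_views(maps[0], maps[1], combine_rule)
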