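"""Volume and label I/O plus sliding-window patch extraction/recomposition.

Coordinate convention, used everywhere in the package: arrays are indexed
``(x, y, z)`` with 0-based voxel indices; ``z`` is the transverse stacking
axis (transverse slices are ``data[:, :, k]``, coronal slices
``data[:, j, :]``).  Supported formats: NIfTI-1 (.nii/.nii.gz), NRRD
(.nrrd/.nhdr), HDF5 (.h5/.hdf5 with datasets "image"/"label").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume", "LabelMap", "PatchGrid",
    "read_volume", "write_volume", "read_labelmap", "write_labelmap",
    "extract_patches", "recompose",
]

_NIFTI = (".nii", ".nii.gz")
_NRRD = (".nrrd", ".nhdr")
_HDF5 = (".h5", ".hdf5")


@dataclass
class Volume:
    """A 3D scalar grid with spacing metadata, axis order (x, y, z)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMap:
    """Integer class indices aligned to a Volume; 0 is background."""

    data: np.ndarray
    num_classes: int = 2

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label map must be 3D, got shape {self.data.shape}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.data.min() < 0 or self.data.max() >= self.num_classes:
            raise ValueError(
                f"label values must lie in [0, {self.num_classes - 1}], "
                f"got range [{self.data.min()}, {self.data.max()}]"
            )

    @property
    def shape(self):
        return self.data.shape


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def _read_array(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    ext = _suffix(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if ext in _NIFTI:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return data, spacing, origin
    if ext in _NRRD:
        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come out (z, y, x); normalize to (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return data, tuple(img.GetSpacing()), tuple(img.GetOrigin())
    if ext in _HDF5:
        with h5py.File(path, "r") as f:
            key = "image" if "image" in f else "label"
            data = f[key][()]
            spacing = tuple(f[key].attrs.get("spacing", (1.0, 1.0, 1.0)))
            origin = tuple(f[key].attrs.get("origin", (0.0, 0.0, 0.0)))
        return data, spacing, origin
    raise ValueError(f"unrecognized volume format: {path.name!r}")


def _write_array(path: Path, data: np.ndarray, spacing, origin, key: str) -> None:
    ext = _suffix(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if ext in _NIFTI:
        affine = np.diag(list(spacing) + [1.0])
        affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(data, affine), str(path))
        return
    if ext in _NRRD:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(spacing))
        img.SetOrigin(tuple(origin))
        sitk.WriteImage(img, str(path))
        return
    if ext in _HDF5:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(key, data=data)
            ds.attrs["spacing"] = spacing
            ds.attrs["origin"] = origin
        return
    raise ValueError(f"unrecognized volume format: {path.name!r}")


def read_volume(path) -> Volume:
    """Read a volume; axis order normalized to (x, y, z)."""
    data, spacing, origin = _read_array(Path(path))
    return Volume(data=data.astype(np.float32), spacing=spacing, origin=origin)


def write_volume(path, volume: Volume) -> None:
    _write_array(Path(path), volume.data, volume.spacing, volume.origin, "image")


def read_labelmap(path, num_classes: int = 2) -> LabelMap:
    data, _, _ = _read_array(Path(path))
    return LabelMap(data=np.rint(data).astype(np.uint8), num_classes=num_classes)


def write_labelmap(path, label: LabelMap) -> None:
    _write_array(Path(path), label.data.astype(np.uint8), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0), "label")


# ----------------------------------------------------------------------
# sliding-window patches
# ----------------------------------------------------------------------

@dataclass
class PatchGrid:
    """Deterministic sliding-window offsets covering a volume.

    Border patches are obtained by shifting the last offset inward so the
    patch shape is always honored (no padding); every voxel is covered.
    """

    patch_shape: tuple[int, int, int]
    stride: tuple[int, int, int]
    offsets: list[tuple[int, int, int]] = field(default_factory=list)

    @classmethod
    def build(cls, volume_shape, patch_shape, stride=None) -> "PatchGrid":
        patch_shape = tuple(int(p) for p in patch_shape)
        if stride is None:
            stride = tuple(max(1, p // 2) for p in patch_shape)
        stride = tuple(int(s) for s in stride)
        if any(s < 1 for s in stride):
            raise ValueError(f"stride must be positive, got {stride}")
        if any(p > v for p, v in zip(patch_shape, volume_shape)):
            raise ValueError(
                f"patch shape {patch_shape} exceeds volume shape {tuple(volume_shape)}"
            )
        per_axis = []
        for v, p, s in zip(volume_shape, patch_shape, stride):
            stops = list(range(0, v - p + 1, s))
            if stops[-1] != v - p:
                stops.append(v - p)
            per_axis.append(stops)
        offsets = sorted(itertools.product(*per_axis))
        return cls(patch_shape=patch_shape, stride=stride, offsets=offsets)


def extract_patches(volume, grid: PatchGrid) -> list[np.ndarray]:
    """Extract the grid's patches from a Volume or 3D array."""
    data = volume.data if isinstance(volume, (Volume, LabelMap)) else np.asarray(volume)
    px, py, pz = grid.patch_shape
    return [data[ox:ox + px, oy:oy + py, oz:oz + pz] for ox, oy, oz in grid.offsets]


def recompose(patches, grid: PatchGrid, out_shape) -> np.ndarray:
    """Fuse per-patch grids back to full resolution by arithmetic mean.

    Patches may be 3D (scalar per voxel) or 4D with a leading class axis.
    Overlapping voxels hold the mean of all contributing patch values.
    """
    patches = [np.asarray(p) for p in patches]
    if len(patches) != len(grid.offsets):
        raise ValueError(
            f"{len(patches)} patches supplied for {len(grid.offsets)} offsets"
        )
    lead = patches[0].shape[:-3]
    for p in patches:
        if p.shape[-3:] != grid.patch_shape or p.shape[:-3] != lead:
            raise ValueError(f"patch shape {p.shape} does not match grid {grid.patch_shape}")
    out = np.zeros(lead + tuple(out_shape), dtype=np.float64)
    count = np.zeros(tuple(out_shape), dtype=np.float64)
    px, py, pz = grid.patch_shape
    for patch, (ox, oy, oz) in zip(patches, grid.offsets):
        out[..., ox:ox + px, oy:oy + py, oz:oz + pz] += patch
        count[ox:ox + px, oy:oy + py, oz:oz + pz] += 1.0
    if (count == 0).any():
        raise ValueError("patch grid does not cover the requested output shape")
    return (out / count).astype(np.float32)
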