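"""Volume I/O and the preprocessing chain down to the canonical 64^3 cube.

Chain: resample to isotropic 1 mm (cubic interpolation) -> robust min-max
normalization inside the brain mask -> crop excessive background using the
mask and zero-pad to 191x158x163 -> downsample to 64x64x64.  Skull stripping
and denoising are not implemented here; a brain mask is a required input
(phantoms ship their own).

Orientation convention used throughout the package: axis 0 = left-right,
axis 2 = inferior-superior, so axial slices are indexed along axis 2.
Masks and annotations must undergo the identical geometric transforms as
their volume; the helpers here take an interpolation ``order`` so binary
images can ride along (re-binarized at 0.5 after interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

TARGET_PAD_SHAPE = (191, 158, 163)
CANONICAL_SHAPE = (64, 64, 64)


class FormatError(ValueError):
    """Unreadable or malformed volume file."""


class PreprocError(ValueError):
    """Invalid input to a preprocessing operation."""


@dataclass
class RawVolume:
    """A 3D intensity array with voxel spacing in mm per axis."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise PreprocError(f"expected a 3D array, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise PreprocError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise PreprocError("volume contains non-finite values")


@dataclass
class Volume:
    """Canonical preprocessed volume: cubic, intensities in [0,1], binary mask."""

    data: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.brain_mask = np.asarray(self.brain_mask)
        if self.data.shape != self.brain_mask.shape:
            raise PreprocError("volume and mask shapes differ")
        if self.data.min() < 0 or self.data.max() > 1:
            raise PreprocError("canonical volume intensities must lie in [0,1]")
        vals = np.unique(self.brain_mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise PreprocError("brain mask must be binary")


def load_volume(path) -> RawVolume:
    """Load a NIfTI volume; spacing is taken from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # nibabel raises several exception types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    return RawVolume(data, spacing)


def save_volume(vol: RawVolume, path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def resample_isotropic(raw: RawVolume, target_mm: float = 1.0, order: int = 3) -> RawVolume:
    """Resample to isotropic spacing with cubic interpolation (order=3).

    The physical extent in mm is preserved to within one voxel per axis.
    """
    if target_mm <= 0:
        raise PreprocError(f"target spacing must be positive, got {target_mm}")
    factors = tuple(s / target_mm for s in raw.spacing)
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return RawVolume(raw.data.copy(), (target_mm,) * 3)
    out = ndimage.zoom(raw.data.astype(np.float64), factors, order=order,
                       mode="nearest", grid_mode=True)
    return RawVolume(out, (target_mm,) * 3)


def normalize(raw: RawVolume, mask: np.ndarray,
              percentiles: tuple[float, float] = (1.0, 99.0)) -> RawVolume:
    """Robust min-max standardization inside the mask; background set to 0.

    In-mask intensities are clipped at the given percentiles and mapped
    linearly to [0, 1].
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise PreprocError("brain mask is empty")
    vals = raw.data[mask]
    lo, hi = np.percentile(vals, percentiles)
    if hi <= lo:
        raise PreprocError("constant image inside mask: cannot normalize")
    out = np.zeros_like(raw.data, dtype=np.float64)
    out[mask] = np.clip((raw.data[mask] - lo) / (hi - lo), 0.0, 1.0)
    return RawVolume(out, raw.spacing)


def _bbox(mask: np.ndarray):
    idx = np.argwhere(mask)
    return idx.min(axis=0), idx.max(axis=0)


def crop_pad(raw: RawVolume, mask: np.ndarray,
             target_shape: tuple[int, int, int] = TARGET_PAD_SHAPE) -> RawVolume:
    """Crop to the brain bounding box, then center it in a zero canvas."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise PreprocError("brain mask is empty")
    lo, hi = _bbox(mask)
    size = hi - lo + 1
    if np.any(size > np.asarray(target_shape)):
        raise PreprocError(
            f"brain extent {tuple(size)} exceeds target {tuple(target_shape)}"
        )
    cropped = raw.data[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    out = np.zeros(target_shape, dtype=raw.data.dtype)
    start = [(t - s) // 2 for t, s in zip(target_shape, size)]
    sl = tuple(slice(st, st + s) for st, s in zip(start, size))
    out[sl] = cropped
    return RawVolume(out, raw.spacing)


def downsample(raw: RawVolume, mask: np.ndarray,
               out_shape: tuple[int, int, int] = CANONICAL_SHAPE,
               order: int = 3) -> Volume:
    """Downsample volume and mask to the canonical shape with one transform.

    The mask rides through the same cubic interpolation and is re-binarized at
    0.5; intensities are clipped back to [0, 1] (cubic overshoot).
    """
    if any(i < o for i, o in zip(raw.data.shape, out_shape)):
        raise PreprocError(
            f"input shape {raw.data.shape} smaller than target {out_shape}"
        )
    factors = tuple(o / i for o, i in zip(out_shape, raw.data.shape))
    data = ndimage.zoom(raw.data.astype(np.float64), factors, order=order,
                        mode="nearest", grid_mode=True)
    m = ndimage.zoom(np.asarray(mask, dtype=np.float64), factors, order=order,
                     mode="nearest", grid_mode=True)
    # zoom output shape can be off by one for awkward ratios; enforce exactly
    data = data[tuple(slice(0, o) for o in out_shape)]
    m = m[tuple(slice(0, o) for o in out_shape)]
    return Volume(np.clip(data, 0.0, 1.0), (m >= 0.5).astype(np.uint8))


def preprocess_case(vol_raw: RawVolume, mask_raw: RawVolume,
                    annotation_raw: RawVolume | None = None,
                    target_mm: float = 1.0,
                    pad_shape: tuple[int, int, int] = TARGET_PAD_SHAPE,
                    out_shape: tuple[int, int, int] = CANONICAL_SHAPE):
    """Run the full chain on one case, transforming mask (and annotation) alike.

    Returns (Volume, annotation or None) in the canonical representation.
    """
    v = resample_isotropic(vol_raw, target_mm)
    m = resample_isotropic(mask_raw, target_mm)
    mask = (m.data >= 0.5)
    v = normalize(v, mask)
    v = crop_pad(v, mask, pad_shape)
    m_c = crop_pad(RawVolume(mask.astype(np.float64), m.spacing), mask, pad_shape)
    ann_c = None
    if annotation_raw is not None:
        a = resample_isotropic(annotation_raw, target_mm)
        ann_c = crop_pad(RawVolume((a.data >= 0.5).astype(np.float64), a.spacing),
                         mask, pad_shape)
    vol = downsample(v, m_c.data >= 0.5, out_shape)
    annotation = None
    if ann_c is not None:
        ann_vol = downsample(ann_c, ann_c.data >= 0.5, out_shape)
        annotation = ann_vol.brain_mask  # binarized transformed annotation
    return vol, annotation


def extract_slices(vol: np.ndarray, axis: int = 2) -> list[np.ndarray]:
    """Ordered axial (default) slices; stacking them reproduces the volume."""
    vol = np.asarray(vol)
    if not (0 <= axis < vol.ndim):
        raise PreprocError(f"axis {axis} invalid for ndim={vol.ndim}")
    return [np.take(vol, i, axis=axis) for i in range(vol.shape[axis])]


def stack_slices(slices, axis: int = 2) -> np.ndarray:
    return np.stack(slices, axis=axis)
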