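"""Synthetic brain phantoms: healthy volumes, inserted lesions, cohorts on disk.

The phantoms emulate the canonical preprocessed representation the models train
on: skull-stripped, intensity-normalized to [0, 1], roughly bilaterally
symmetric brain-shaped volumes (default 64x64x64) with a binary brain mask.
Axis conventions follow the rest of the package: axis 0 is left-right, axis 2
is inferior-superior (axial slices are indexed along axis 2).

Anatomy is deliberately simple but learnably structured: an outer ellipsoid
"brain" with mirrored pairs of internal ellipsoidal substructures (dark
ventricle-like cavities, bright white-matter-like bands), smoothed with a
Gaussian kernel.  Lesions are smoothly perturbed blobs rather than perfect
spheres so a reconstruction network cannot memorize a single shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preproc import RawVolume, save_volume

MANIFEST_COLUMNS = ["path", "mask_path", "annotation_path", "role", "seed"]


class PhantomError(ValueError):
    """Invalid phantom/lesion specification or impossible placement."""


@dataclass
class PhantomSpec:
    """Parameters of a healthy brain phantom.

    noise_sigma is the std of additive intensity noise inside the brain mask;
    symmetry_jitter is the maximum voxel displacement applied per hemisphere to
    substructure centers, breaking perfect left-right symmetry.
    """

    grid_size: int = 64
    brain_axes: tuple[float, float, float] | None = None
    n_substructures: int = 3
    noise_sigma: float = 0.02
    symmetry_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 16:
            raise PhantomError(f"grid_size must be >= 16, got {self.grid_size}")
        if not (0.0 <= self.noise_sigma < 0.5):
            raise PhantomError("noise_sigma must be in [0, 0.5)")
        if self.brain_axes is None:
            g = self.grid_size
            self.brain_axes = (0.42 * g, 0.36 * g, 0.38 * g)
        if any(a <= 0 for a in self.brain_axes):
            raise PhantomError("brain_axes must be positive")
        if 2 * max(self.brain_axes) >= self.grid_size:
            raise PhantomError("brain ellipsoid does not fit inside the grid")
        if self.symmetry_jitter < 0:
            raise PhantomError("symmetry_jitter must be >= 0")


@dataclass
class LesionSpec:
    """Parameters of inserted lesions (annotation ground truth).

    intensity_shift is the signed contrast added inside the lesion, in [-1, 1];
    texture_sigma controls the smoothness of the interior contrast modulation
    (0 means a flat shift).
    """

    n_lesions: int = 1
    radius_range: tuple[float, float] = (4.0, 8.0)
    intensity_shift: float = 0.4
    texture_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_lesions < 1:
            raise PhantomError("n_lesions must be >= 1")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise PhantomError("radius_range must satisfy 0 < min <= max")
        if not (-1.0 <= self.intensity_shift <= 1.0):
            raise PhantomError("intensity_shift must be in [-1, 1]")
        if self.texture_sigma < 0:
            raise PhantomError("texture_sigma must be >= 0")


def _coords(n: int):
    """Symmetric voxel coordinates: flipping axis 0 maps x -> -x exactly."""
    c = np.arange(n) - (n - 1) / 2.0
    return np.meshgrid(c, c, c, indexing="ij", sparse=True)


def _ellipsoid(x, y, z, center, axes):
    cx, cy, cz = center
    ax, ay, az = axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def generate_healthy(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate a healthy phantom volume and its binary brain mask.

    Returns (volume, mask): volume is float32 in [0, 1], zero outside the mask;
    with noise_sigma=0 and symmetry_jitter=0 the volume equals its own
    left-right mirror exactly.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.grid_size
    x, y, z = _coords(g)
    mask = _ellipsoid(x, y, z, (0.0, 0.0, 0.0), spec.brain_axes)

    vol = np.where(mask, 0.55, 0.0)
    ax0, ax1, ax2 = spec.brain_axes

    def jitter():
        if spec.symmetry_jitter == 0:
            return np.zeros(3)
        return rng.uniform(-spec.symmetry_jitter, spec.symmetry_jitter, size=3)

    def paint_pair(center, axes, value):
        """Paint a substructure and its mirror (jittered independently)."""
        cx, cy, cz = center
        for side in (+1, -1):
            c = np.array([side * cx, cy, cz], dtype=float) + jitter()
            region = _ellipsoid(x, y, z, c, axes) & mask
            vol[region] = value

    # deterministic, spec-driven internal anatomy: a bright white-matter-like
    # shell band, then alternating dark/bright mirrored pairs
    paint_pair((0.45 * ax0, 0.0, 0.0), (0.38 * ax0, 0.62 * ax1, 0.66 * ax2), 0.75)
    structures = [
        ((0.18 * ax0, 0.05 * ax1, 0.05 * ax2), (0.14 * ax0, 0.30 * ax1, 0.34 * ax2), 0.15),
        ((0.52 * ax0, -0.30 * ax1, 0.15 * ax2), (0.12 * ax0, 0.18 * ax1, 0.20 * ax2), 0.35),
        ((0.40 * ax0, 0.35 * ax1, -0.25 * ax2), (0.10 * ax0, 0.16 * ax1, 0.16 * ax2), 0.90),
        ((0.25 * ax0, -0.15 * ax1, -0.40 * ax2), (0.10 * ax0, 0.22 * ax1, 0.14 * ax2), 0.30),
        ((0.60 * ax0, 0.20 * ax1, 0.30 * ax2), (0.08 * ax0, 0.12 * ax1, 0.12 * ax2), 0.85),
    ]
    for center, axes, value in structures[: spec.n_substructures]:
        paint_pair(center, axes, value)

    vol = ndimage.gaussian_filter(vol, sigma=1.2, mode="constant")
    if spec.noise_sigma > 0:
        vol = vol + spec.noise_sigma * rng.standard_normal(vol.shape)
    vol = np.where(mask, np.clip(vol, 0.05, 1.0), 0.0)
    return vol.astype(np.float32), mask.astype(np.uint8)


def _lesion_blob(shape, center, radius, rng) -> np.ndarray:
    """Binary blob: a sphere whose radius is modulated by a smooth random field."""
    idx = [np.arange(n) - c for n, c in zip(shape, center)]
    xx, yy, zz = np.meshgrid(*idx, indexing="ij", sparse=True)
    dist = np.sqrt(xx**2 + yy**2 + zz**2)
    bump = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0,
                                   mode="constant")
    scale = np.max(np.abs(bump)) or 1.0
    local_radius = radius * (1.0 + 0.3 * bump / scale)
    return dist <= local_radius


def insert_lesions(
    vol: np.ndarray,
    mask: np.ndarray,
    lspec: LesionSpec,
    max_retries: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Insert lesions strictly inside the brain mask.

    Returns (lesioned volume, annotation mask).  Voxels outside the annotation
    are bit-identical to the input; modified intensities are clipped to [0, 1]
    (not renormalized) to preserve healthy background statistics.
    """
    rng = np.random.default_rng(lspec.seed)
    vol = np.asarray(vol)
    mask = np.asarray(mask).astype(bool)
    out = vol.copy()
    annotation = np.zeros(vol.shape, dtype=np.uint8)

    for _ in range(lspec.n_lesions):
        radius = rng.uniform(*lspec.radius_range)
        eroded = ndimage.binary_erosion(
            mask, iterations=max(1, int(np.ceil(radius)))
        )
        candidates = np.argwhere(eroded & ~annotation.astype(bool))
        placed = False
        for _attempt in range(max_retries):
            if len(candidates) == 0:
                break
            center = candidates[rng.integers(len(candidates))]
            blob = _lesion_blob(vol.shape, center, radius, rng) & mask
            if blob.any():
                annotation |= blob.astype(np.uint8)
                placed = True
                break
        if not placed:
            raise PhantomError(
                f"could not place a lesion of radius {radius:.1f} inside the mask"
            )

    region = annotation.astype(bool)
    if lspec.intensity_shift != 0.0 and region.any():
        texture = np.ones(vol.shape)
        if lspec.texture_sigma > 0:
            t = ndimage.gaussian_filter(
                rng.standard_normal(vol.shape), sigma=lspec.texture_sigma
            )
            peak = np.max(np.abs(t)) or 1.0
            texture = 1.0 + 0.4 * t / peak
        out[region] = np.clip(
            vol[region] + lspec.intensity_shift * texture[region], 0.0, 1.0
        ).astype(vol.dtype)
    return out, annotation


def _child_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    n_healthy: int,
    n_lesioned: int,
    spec: PhantomSpec,
    lspec: LesionSpec,
    seed: int,
    out_dir,
    healthy_val_fraction: float = 0.2,
    lesioned_test_fraction: float = 0.5,
) -> pd.DataFrame:
    """Write a phantom cohort as NIfTI files plus a CSV manifest.

    Healthy subjects are split train / val-healthy; lesioned subjects are split
    val-anom (threshold calibration) / test.  Per-subject seeds are derived
    deterministically from the master seed, so two runs with the same arguments
    produce identical files and manifests.
    """
    if n_healthy < 0 or n_lesioned < 0:
        raise PhantomError("cohort counts must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    n_val_h = int(round(healthy_val_fraction * n_healthy))
    n_test = int(round(lesioned_test_fraction * n_lesioned))

    for i in range(n_healthy):
        sseed = _child_seed(seed, i)
        s = PhantomSpec(**{**spec.__dict__, "seed": sseed})
        vol, mask = generate_healthy(s)
        stem = f"healthy_{i:04d}"
        vpath, mpath = out_dir / f"{stem}.nii.gz", out_dir / f"{stem}_mask.nii.gz"
        save_volume(RawVolume(vol, (1.0, 1.0, 1.0)), vpath)
        save_volume(RawVolume(mask.astype(np.float32), (1.0, 1.0, 1.0)), mpath)
        role = "val-healthy" if i >= n_healthy - n_val_h else "train"
        rows.append([str(vpath), str(mpath), "", role, sseed])

    for j in range(n_lesioned):
        sseed = _child_seed(seed, n_healthy + j)
        s = PhantomSpec(**{**spec.__dict__, "seed": sseed})
        ls = LesionSpec(**{**lspec.__dict__, "seed": sseed + 1})
        vol, mask = generate_healthy(s)
        vol, annotation = insert_lesions(vol, mask, ls)
        stem = f"lesioned_{j:04d}"
        vpath = out_dir / f"{stem}.nii.gz"
        mpath = out_dir / f"{stem}_mask.nii.gz"
        apath = out_dir / f"{stem}_annotation.nii.gz"
        save_volume(RawVolume(vol, (1.0, 1.0, 1.0)), vpath)
        save_volume(RawVolume(mask.astype(np.float32), (1.0, 1.0, 1.0)), mpath)
        save_volume(RawVolume(annotation.astype(np.float32), (1.0, 1.0, 1.0)), apath)
        role = "test" if j >= n_lesioned - n_test else "val-anom"
        rows.append([str(vpath), str(mpath), str(apath), role, sseed])

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
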