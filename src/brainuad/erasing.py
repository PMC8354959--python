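"""Spatial input-erasing augmentations (2D and 3D, zero or noise fill).

During training a region of the network *input* is blanked while the
optimization target stays bit-identical to the original image, so the model
must in-paint the missing content from its surroundings.  Three strategies
are provided, each rank-generic:

* ``single`` — one axis-aligned patch (2D) or cuboid (3D) with a nominal size
  drawn between 1% and 25% of the total element count;
* ``multi``  — up to ``max_regions`` patches/cuboids whose summed nominal size
  stays inside the same budget;
* ``half``   — one lateral brain half (axis 0) erased, in the whole slice (2D)
  or in a contiguous axial slab of 1..32 slices (3D).

Erasing fires with probability ``apply_prob`` (default 0.5) so unmodified
images are still seen.  The erased region is filled either with exact zeros or
with noise resampled from the image's own intensity distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRATEGIES = ("none", "single", "multi", "half")
FILLS = ("zero", "noise")


class ErasingError(ValueError):
    pass


@dataclass
class ErasingConfig:
    strategy: str = "single"
    fill: str = "zero"
    apply_prob: float = 0.5
    budget_range: tuple[float, float] = (0.01, 0.25)
    max_regions: int = 10
    slab_range: tuple[int, int] = (1, 32)

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ErasingError(f"unknown strategy {self.strategy!r}")
        if self.fill not in FILLS:
            raise ErasingError(f"unknown fill mode {self.fill!r}")
        if not (0.0 <= self.apply_prob <= 1.0):
            raise ErasingError("apply_prob must be in [0, 1]")
        lo, hi = self.budget_range
        if not (0.0 < lo <= hi < 1.0):
            raise ErasingError("budget_range must satisfy 0 < min <= max < 1")
        if self.max_regions < 1:
            raise ErasingError("max_regions must be >= 1")
        s_lo, s_hi = self.slab_range
        if not (1 <= s_lo <= s_hi):
            raise ErasingError("slab_range must satisfy 1 <= min <= max")


@dataclass
class ErasedSample:
    """input: the (possibly) erased image; target: untouched original copy."""

    input: np.ndarray
    target: np.ndarray
    erase_mask: np.ndarray
    nominal_fraction: float = 0.0
    n_regions: int = 0
    slab_thickness: int = 0


def fill_region(img: np.ndarray, erase_mask: np.ndarray, fill: str, rng) -> np.ndarray:
    """Return a copy of img with the masked elements replaced.

    ``zero`` writes exact 0.0; ``noise`` writes i.i.d. draws (with replacement)
    from the multiset of the image's own element values.
    """
    out = img.copy()
    m = erase_mask.astype(bool)
    n = int(m.sum())
    if n == 0:
        return out
    if fill == "zero":
        out[m] = 0.0
    elif fill == "noise":
        out[m] = rng.choice(img.ravel(), size=n, replace=True)
    else:
        raise ErasingError(f"unknown fill mode {fill!r}")
    return out


def _draw_region_sides(shape, target_voxels, rng):
    """Integer side lengths with product ~= target_voxels, varied aspect ratio.

    Per-axis lengths are drawn log-uniformly, rescaled so their product hits
    the drawn budget, rounded, then nudged so the nominal (pre-clip) size never
    leaves [1, prod(shape)].
    """
    d = len(shape)
    raw = np.exp(rng.uniform(0.0, 1.0, size=d))
    raw *= (target_voxels / np.prod(raw)) ** (1.0 / d)
    sides = np.maximum(1, np.round(raw).astype(int))
    sides = np.minimum(sides, np.asarray(shape))
    return sides


def _adjust_total(regions, shape, lo_vox, hi_vox):
    """Nudge integer side lengths until the summed nominal size is in bounds."""
    def total():
        return sum(int(np.prod(s)) for s in regions)

    guard = 0
    while total() > hi_vox and guard < 10000:
        # shrink the largest side of the largest region
        i = int(np.argmax([np.prod(s) for s in regions]))
        j = int(np.argmax(regions[i]))
        if regions[i][j] > 1:
            regions[i][j] -= 1
        guard += 1
    guard = 0
    while total() < lo_vox and guard < 10000:
        i = int(np.argmin([np.prod(s) for s in regions]))
        grown = False
        for j in np.argsort(regions[i]):
            if regions[i][j] < shape[j]:
                regions[i][j] += 1
                grown = True
                break
        if not grown:
            break
        guard += 1
    return regions


def _place_region(shape, sides, rng):
    """Center uniform over the image; the region is clipped at the borders."""
    center = np.array([rng.integers(0, n) for n in shape])
    lo = center - sides // 2
    hi = lo + sides
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(shape))
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def _erase_regions(img, cfg, rng, n_regions):
    shape = img.shape
    n_total = img.size
    lo_f, hi_f = cfg.budget_range
    lo_vox = int(np.ceil(lo_f * n_total))
    hi_vox = int(np.floor(hi_f * n_total))
    total_target = rng.uniform(lo_f, hi_f) * n_total
    if n_regions == 1:
        targets = [total_target]
    else:
        weights = rng.dirichlet(np.ones(n_regions))
        targets = [max(1.0, w * total_target) for w in weights]
    regions = [_draw_region_sides(shape, t, rng) for t in targets]
    regions = _adjust_total(regions, shape, lo_vox, hi_vox)
    erase_mask = np.zeros(shape, dtype=bool)
    for sides in regions:
        erase_mask[_place_region(shape, sides, rng)] = True
    nominal = sum(int(np.prod(s)) for s in regions)
    out = ErasedSample(
        input=fill_region(img, erase_mask, cfg.fill, rng),
        target=img.copy(),
        erase_mask=erase_mask,
        nominal_fraction=nominal / n_total,
        n_regions=n_regions,
    )
    return out


def erase_single(img: np.ndarray, cfg: ErasingConfig, rng) -> ErasedSample:
    """One randomly located and sized patch (2D) / cube (3D)."""
    return _erase_regions(np.asarray(img), cfg, rng, 1)


def erase_multi(img: np.ndarray, cfg: ErasingConfig, rng) -> ErasedSample:
    """1..max_regions regions; the summed nominal size stays in the budget."""
    n = int(rng.integers(1, cfg.max_regions + 1))
    return _erase_regions(np.asarray(img), cfg, rng, n)


def erase_half(img: np.ndarray, cfg: ErasingConfig, rng) -> ErasedSample:
    """Erase one lateral half (axis 0 = left-right) of the brain.

    2D: the whole half of the slice.  3D: the half within a contiguous axial
    slab (axis 2) of k slices, k uniform in slab_range.
    """
    img = np.asarray(img)
    mid = img.shape[0] // 2
    left = bool(rng.integers(0, 2))
    erase_mask = np.zeros(img.shape, dtype=bool)
    lateral = slice(0, mid) if left else slice(mid, img.shape[0])
    slab_k = 0
    if img.ndim == 2:
        erase_mask[lateral, :] = True
    elif img.ndim == 3:
        s_lo, s_hi = cfg.slab_range
        if s_hi > img.shape[2]:
            raise ErasingError(
                f"slab_range {cfg.slab_range} exceeds axial extent {img.shape[2]}"
            )
        slab_k = int(rng.integers(s_lo, s_hi + 1))
        start = int(rng.integers(0, img.shape[2] - slab_k + 1))
        erase_mask[lateral, :, start:start + slab_k] = True
    else:
        raise ErasingError("erase_half expects a 2D or 3D image")
    return ErasedSample(
        input=fill_region(img, erase_mask, cfg.fill, rng),
        target=img.copy(),
        erase_mask=erase_mask,
        nominal_fraction=float(erase_mask.mean()),
        n_regions=1,
        slab_thickness=slab_k if img.ndim == 3 else img.shape[0] - mid,
    )


_DISPATCH = {"single": erase_single, "multi": erase_multi, "half": erase_half}


def apply_erasing(img: np.ndarray, cfg: ErasingConfig, rng) -> ErasedSample:
    """Dispatch to the configured strategy with probability apply_prob.

    With probability 1 - apply_prob (and always for strategy 'none') the input
    passes through unmodified with an empty erase mask.
    """
    img = np.asarray(img)
    if cfg.strategy == "none" or rng.random() >= cfg.apply_prob:
        return ErasedSample(
            input=img.copy(),
            target=img.copy(),
            erase_mask=np.zeros(img.shape, dtype=bool),
        )
    if cfg.strategy not in _DISPATCH:
        raise ErasingError(f"unknown strategy {cfg.strategy!r}")
    return _DISPATCH[cfg.strategy](img, cfg, rng)
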