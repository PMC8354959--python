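"""Residual-based anomaly segmentation with greedy threshold calibration.

A trained model reconstructs a test volume; the voxel-wise l1 residual
|x - x_hat| is multiplied by a slightly eroded brain mask (reconstruction
errors pile up at the sharp mask boundary) and median-filtered to remove
isolated outliers.  The residual is binarized at a threshold calibrated on an
*annotated* validation set by a greedy bisection of [0, 1]: each iteration
probes the two quartile points of the current interval, scores them by
dataset-pooled Dice, keeps the better half, and after 10 iterations the best
probed threshold wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .metrics import dice_dataset
from .preproc import extract_slices, stack_slices


class SegmentationError(ValueError):
    pass


@dataclass
class ThresholdSearchResult:
    best_threshold: float
    trace: list[tuple[float, float]]  # (threshold, dataset Dice in [0,1] scale)
    final_interval: tuple[float, float]


def residual_map(x: np.ndarray, x_hat: np.ndarray) -> np.ndarray:
    """Voxel-wise l1 residual |x - x_hat|."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise SegmentationError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return np.abs(x - x_hat)


def postprocess(res: np.ndarray, mask: np.ndarray,
                erosion_radius: int = 1, median_size: int = 3) -> np.ndarray:
    """Multiply by an eroded brain mask, then median-filter small outliers.

    Erosion uses the face-connected (6-neighbourhood in 3D) structuring
    element, applied ``erosion_radius`` times; outside the eroded mask the
    residual is exactly zero.
    """
    res = np.asarray(res, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if res.shape != mask.shape:
        raise SegmentationError("residual and mask shapes differ")
    eroded = mask
    if erosion_radius > 0:
        structure = ndimage.generate_binary_structure(res.ndim, 1)
        eroded = ndimage.binary_erosion(mask, structure=structure,
                                        iterations=erosion_radius)
        if not eroded.any():
            raise SegmentationError("erosion emptied the brain mask")
    out = res * eroded
    if median_size > 1:
        out = ndimage.median_filter(out, size=median_size)
        out = out * eroded
    return out


def binarize(res: np.ndarray, threshold: float) -> np.ndarray:
    """Segmentation mask: residual strictly above the threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise SegmentationError("threshold must be in [0, 1]")
    return (np.asarray(res) > threshold).astype(np.uint8)


def greedy_threshold_search(residuals, annotations,
                            iterations: int = 10) -> ThresholdSearchResult:
    """Greedy bisection of [0, 1] for the binarization threshold.

    Per iteration the quartile points a + 0.25(b-a) and a + 0.75(b-a) of the
    current interval [a, b] are scored by dataset-pooled Dice over all
    residual/annotation pairs; the interval shrinks to the half whose probe
    scored better (ties keep the lower half).  Returns the best probed
    threshold, the full probe trace and the final interval.
    """
    residuals = [np.asarray(r) for r in residuals]
    annotations = [np.asarray(a) for a in annotations]
    if len(residuals) == 0 or len(residuals) != len(annotations):
        raise SegmentationError("need aligned, non-empty residual/annotation lists")

    def score(t: float) -> float:
        preds = [binarize(r, t) for r in residuals]
        return dice_dataset(preds, annotations) / 100.0

    a, b = 0.0, 1.0
    trace: list[tuple[float, float]] = []
    for _ in range(iterations):
        t_lo = a + 0.25 * (b - a)
        t_hi = a + 0.75 * (b - a)
        d_lo, d_hi = score(t_lo), score(t_hi)
        trace.append((t_lo, d_lo))
        trace.append((t_hi, d_hi))
        if d_lo >= d_hi:
            b = (a + b) / 2.0
        else:
            a = (a + b) / 2.0
    best_threshold, _ = max(trace, key=lambda pair: (pair[1], -pair[0]))
    return ThresholdSearchResult(best_threshold=float(best_threshold),
                                 trace=trace, final_interval=(a, b))


def reconstruct_volume(model, vol: np.ndarray) -> np.ndarray:
    """Posterior-mean reconstruction; rank-2 models run per axial slice."""
    vol = np.asarray(vol, dtype=np.float32)
    if model.cfg.rank == 3:
        return model.reconstruct(vol[None])[0]
    slices = extract_slices(vol, axis=2)
    recon = model.reconstruct(np.stack(slices, axis=0))
    return stack_slices(list(recon), axis=2)


def segment_volume(model, vol: np.ndarray, mask: np.ndarray, threshold: float,
                   erosion_radius: int = 1, median_size: int = 3):
    """Full chain reconstruct -> residual -> postprocess -> binarize.

    Returns (segmentation mask, post-processed residual map).  Deterministic:
    reconstruction always uses the posterior mean.
    """
    x_hat = reconstruct_volume(model, vol)
    res = residual_map(vol, x_hat)
    res = postprocess(res, mask, erosion_radius, median_size)
    return binarize(res, threshold), res
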