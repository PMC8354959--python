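"""Residual-based anomaly segmentation end to end, at example scale.

Trains a small VAE on healthy phantoms, calibrates the binarization
threshold with the greedy search on annotated calibration phantoms, then
segments held-out lesioned phantoms and reports DICE and AUPRC.  For the
full-scale version of this study see `brainuad.study.run_phantom_study`.
"""

import numpy as np

from brainuad.erasing import ErasingConfig
from brainuad.metrics import evaluate_segmentation
from brainuad.phantom import LesionSpec, PhantomSpec, generate_healthy, insert_lesions
from brainuad.segment import (
    binarize,
    greedy_threshold_search,
    postprocess,
    reconstruct_volume,
    residual_map,
)
from brainuad.trainer import TrainConfig, train
from brainuad.vae import NetworkConfig

GRID = 32


def healthy(seed):
    return generate_healthy(PhantomSpec(grid_size=GRID, noise_sigma=0.02,
                                        symmetry_jitter=1.0, seed=seed))


def lesioned(seed):
    vol, mask = healthy(seed)
    lvol, ann = insert_lesions(vol, mask,
                               LesionSpec(n_lesions=1, radius_range=(2.5, 5.0),
                                          intensity_shift=0.4, seed=seed + 1))
    return lvol, mask, ann


print("generating cohorts ...")
train_set = [healthy(i)[0] for i in range(40)]
val_set = [healthy(100 + i)[0] for i in range(5)]
calib = [lesioned(200 + i) for i in range(5)]
test = [lesioned(300 + i) for i in range(5)]

print("training ...")
model, log = train(
    train_set, val_set,
    NetworkConfig(rank=3, input_extent=GRID, latent_dim=32,
                  stage_channels=(8, 16, 32), seed=0),
    TrainConfig(batch_size=8, max_epochs=8, kl_weight=1.0 / GRID**3,
                erasing=ErasingConfig("single", fill="noise"), seed=0))


def residual(vol, mask):
    res = residual_map(vol, reconstruct_volume(model, vol))
    return postprocess(res, mask, erosion_radius=1, median_size=3)


print("calibrating threshold ...")
search = greedy_threshold_search([residual(v, m) for v, m, _ in calib],
                                 [a for _, _, a in calib])
t = search.best_threshold
print(f"best threshold {t:.4f}")

preds = [binarize(residual(v, m), t) for v, m, _ in test]
report = evaluate_segmentation(preds, [a for _, _, a in test],
                               residuals=[residual(v, m) for v, m, _ in test])
print(f"\nDICE_D {report.dice_dataset:.1f}   "
      f"DICE_S {report.dice_subject_mean:.1f} +/- {report.dice_subject_std:.1f}   "
      f"AUPRC {report.auprc_voxel:.1f}")
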