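# Methods note

This note records the model, the synthetic data generator, and the numerical
and implementation choices behind `brainuad`, including deliberate deviations
from common defaults and the package's known limitations.

## Problem setting

Unsupervised anomaly segmentation: a variational autoencoder (VAE) is trained
exclusively on healthy brain volumes and asked to reconstruct unseen data.
Lesions, being absent from the training distribution, reconstruct poorly; the
voxel-wise l1 residual `|x - x_hat|` between input and reconstruction is the
anomaly score. A binarization threshold on the post-processed residual is
calibrated on a small annotated validation set, and held-out volumes are
segmented by thresholding.

## Model

Encoder: a stack of strided convolutions (kernel 4, stride 2, padding 1),
each followed by LeakyReLU(0.2), halving the spatial extent per stage while
increasing channels (default 32, 64, 128, 256). Two dense heads map the
flattened features to the posterior mean and log-variance. Decoder: a dense
layer back to the bottleneck feature map, then mirrored transposed
convolutions doubling the extent per stage, ending in a bounded output
activation. The 2D and 3D models are structurally identical — same stages,
same channels — only the operator rank differs; default latent sizes are 128
(2D) and 512 (3D).

Loss: mean-reduced l1 reconstruction error plus `kl_weight` times the
batch-mean KL divergence between the diagonal-Gaussian posterior and the
standard normal, `0.5 * sum(mu^2 + e^logvar - 1 - logvar)`. Training uses the
reparameterization trick; reconstruction at test time is deterministic
(posterior mean, no sampling). Optimizer: Adam, learning rate 0.001, batch
size 32. The training epoch is selected by the lowest reconstruction error
on held-out *healthy* volumes; annotated data never influences training.

### Spatial input erasing

During training, with probability 0.5 per sample, regions of the *input* are
erased while the reconstruction target stays bit-identical to the original —
an in-painting task that forces the model to use global context:

* `single`: one box (square/cube-like, log-uniform side ratios) covering
  1–25% of the image;
* `multi`: up to 10 boxes sharing a 1–25% total budget (Dirichlet split);
* `half`: one half of the image along the left–right axis in 2D; in 3D an
  axial slab of 1–32 slices;
* fill: constant zero, or values resampled from the image's own intensity
  distribution (`noise`).

### Numpy network core

No GPU deep-learning framework is required: convolutions, transposed
convolutions, dense layers, activations, backpropagation and Adam are
implemented in `brainuad.vae.nn` on numpy. Convolution uses an im2col
layout built from `sliding_window_view` with a single copy, so forward and
backward passes are BLAS matrix products; `col2im` is a set of strided
slice-adds. Gradients are verified against central finite differences in
the test suite (full-model check, float64, tolerance 2e-4). Transposed
convolution is the exact adjoint of the strided convolution, which is why
`kernel_size` must be even: with stride 2 and padding `(k-2)/2` every
decoder stage exactly doubles the extent, mirroring the encoder.

### Output activation (deviation)

A logistic sigmoid output is the conventional choice for [0,1] images, and
remains available (`output_activation="sigmoid"`). It is **not** the
default. With mean-l1 loss, Adam, and images whose background is exactly
zero over ~3/4 of the voxels, the sigmoid saturates: the constant l1 sign
gradient from the background pushes shared pre-activations to large negative
values, the sigmoid derivative vanishes everywhere, and the reconstruction
collapses to all zeros (observed in-mask reconstruction ~1e-13 after ~100
steps). The default is therefore a bounded-linear clip, `clip(x, 0, 1)`,
whose gradient is 1 inside the open interval and 0 outside: it reaches the
exact background value and switches its gradient off cleanly instead of
saturating. Output range [0,1] is preserved either way.

### KL weight

The library default is `kl_weight=1.0`. The phantom study and the examples
pass `kl_weight = 1/n_voxels`, which makes mean-reduced l1 plus
latent-summed KL equivalent (up to a constant factor) to the canonical
summed evidence lower bound. With `kl_weight=1.0` and a mean-reduced
reconstruction term the KL dominates by orders of magnitude and the
posterior collapses to the prior.

## Segmentation and calibration

Residuals are post-processed by (1) multiplying with the brain mask eroded
by a radius-1, 6-connectivity structuring element (configurable), removing
skull-boundary artifacts, and (2) a 3-per-axis median filter suppressing
isolated hot voxels. The binarization threshold is found by a greedy
bisection: starting from [0, 1], each iteration scores the thresholds at
the current interval's lower and upper quartile points by dataset-pooled
DICE over the calibration set, keeps the lower half on a lower-quartile win
or tie and the upper half otherwise, and after 10 iterations returns the
best probed threshold (final interval width 2^-10).

A property worth knowing: this half-interval cut tracks the DICE(t) maximum
reliably only when the profile falls off (approximately) symmetrically on
both sides of its peak — then the quartile probe closer to the peak always
wins and the kept half always contains it. On unimodal but strongly
asymmetric profiles (e.g. a steep false-positive cliff below the optimum and
a gentle true-positive slope above it) an early comparison can discard the
half containing the peak; the search still returns the best threshold it
probed. The acceptance fixtures for the grid-oracle equivalence are built
by quantile inversion of an explicitly symmetric target profile for exactly
this reason; on arbitrary profiles only the best-probed guarantee holds.

## Metrics

* `DICE_D` (dataset): one DICE over the voxel sets pooled across subjects.
* `DICE_S` (subject): mean ± population standard deviation of per-subject
  DICE. Both-empty sets define DICE 1.0 so the statistic is total.
* `AUPRC`: step-wise average precision (sum of precision times recall
  increments over descending unique scores), matching an exhaustive
  per-threshold sweep to 1e-9; computed voxel-wise on residuals and
  slice-wise for detection.
* Slice-wise detection: a slice is anomalous if its annotation contains any
  lesion voxel; its score is the mean in-mask absolute residual.

## Synthetic phantom generator

Healthy phantoms are bilaterally symmetric ellipsoidal "brains" with three
mirrored internal substructures, Gaussian-smoothed, with additive in-mask
noise (sigma 0.02) and per-side placement jitter breaking perfect symmetry;
intensities are clipped to [0.05, 1] inside the mask and exactly 0 outside.
With jitter and noise set to zero the phantom is an exact mirror fixed
point, which the tests exploit. Lesions are spheres whose radius is
modulated ±30% by a smoothed noise field, placed wholly inside the eroded
brain mask, added as a texture-modulated intensity shift (default +0.4) and
recorded voxel-exactly in the annotation mask.

Realism and limits: the phantoms reproduce the *task structure* —
skull-stripped [0,1] volumes, bilateral symmetry, low-texture parenchyma,
focal hyperintense lesions — not anatomy. There is no cortex/CSF geometry,
no MRI noise model (Rician), no bias field, no partial-volume effect.
Results on phantoms demonstrate that the pipeline recovers inserted
anomalies; they say nothing quantitative about clinical data.

## End-to-end study (`brainuad.study`)

`run_phantom_study(seed)` runs the whole method at desk scale: 32^3
phantoms; 170 training and 30 healthy-validation subjects; a reduced 3D VAE
(latent 64, channels 16/32/64/128) trained up to 25 epochs with
single-region noise-filled erasing; threshold calibration on 20 lesioned
phantoms; evaluation on 20 held-out lesioned phantoms. Two null baselines
anchor the result: predicting the entire eroded brain positive, and
binarizing per-subject shuffled residuals at the same threshold. All
randomness derives from the single seed through independent spawned
streams. Reference result (seed 1, one CPU core, ~6 min): DICE_S
86.5 ± 5.5, DICE_D 89.7, voxel AUPRC 88.8, slice AUPRC 90.9, against
baselines 5.9 and 2.9; mean lesion residual 0.340 vs healthy 0.047.

The 32^3 scale (rather than 64^3) and the 25-epoch budget are runtime
choices for single-core numpy training; the epoch budget was set from the
healthy-validation curve (still improving through ~epoch 24), never from
test outcomes.

## Numerical choices

* All statistics accumulate in float64; network weights are float32.
* Log-variances are clipped to ±10 before exponentiation.
* Reproducibility: every stochastic component takes an explicit
  `numpy.random.Generator` or integer seed; independent streams are derived
  via `SeedSequence` spawn keys, so adding subjects or stages never shifts
  another stream.

## Limitations

* Pure-numpy training is single-core and slow; 64^3 3D training at
  realistic cohort sizes is out of reach. The architecture supports it; the
  runtime does not.
* The generator's simplicity means absolute metric values on phantoms are
  far higher than anything achievable on clinical data.
* Skull stripping and denoising are out of scope; brain masks are inputs.
* No connected-component filtering or other shape-aware post-processing of
  segmentations.
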