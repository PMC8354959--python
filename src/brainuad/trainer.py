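"""Training loop: healthy-only data, erasing on inputs, epoch selection on
healthy-validation reconstruction error.

Erasing is applied to the network *input* per sample; the loss is always
computed against the unmodified image, so every erased batch is an in-painting
problem.  After each epoch the un-erased validation reconstruction l1 (with
z = mu) is logged; the returned checkpoint is the weights of the epoch with
the lowest validation error.  Everything is seeded, single-threaded numpy, so
two runs with the same configuration are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .erasing import ErasingConfig, apply_erasing
from .preproc import extract_slices
from .vae import VAE, NetworkConfig, recon_l1
from .vae.nn import Adam


class TrainingError(ValueError):
    pass


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 0.001
    optimizer: str = "adam"
    max_epochs: int = 20
    erasing: ErasingConfig = field(default_factory=lambda: ErasingConfig("none"))
    kl_weight: float = 1.0
    subset_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise TrainingError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise TrainingError("learning_rate must be positive")
        if self.optimizer.lower() != "adam":
            raise TrainingError(f"unsupported optimizer {self.optimizer!r}")
        if not (0.0 < self.subset_fraction <= 1.0):
            raise TrainingError("subset_fraction must be in (0, 1]")


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    train_recon: list[float] = field(default_factory=list)
    train_kl: list[float] = field(default_factory=list)
    val_recon: list[float] = field(default_factory=list)
    selected_epoch: int = -1  # 0-based index into the per-epoch lists


def select_subset(items, fraction: float, seed: int):
    """Seed-deterministic nested subsets: subset(f1) ⊆ subset(f2) for f1 <= f2.

    One fixed seeded shuffle orders the items; a fraction f takes the first
    ceil(f * n) of that order, so smaller fractions are prefixes of larger.
    """
    items = list(items)
    order = np.random.default_rng(seed).permutation(len(items))
    k = int(np.ceil(fraction * len(items)))
    return [items[i] for i in order[:k]]


def make_2d_training_stream(volumes, rng) -> list[np.ndarray]:
    """All axial slices (axis 2) of all volumes, shuffled with the run seed."""
    slices = []
    for vol in volumes:
        slices.extend(extract_slices(np.asarray(vol), axis=2))
    order = rng.permutation(len(slices))
    return [slices[i] for i in order]


def _validation_recon(model: VAE, val_items, batch_size: int) -> float:
    errs = []
    for start in range(0, len(val_items), batch_size):
        batch = np.stack(val_items[start:start + batch_size]).astype(np.float32)
        x_hat = model.reconstruct(batch)
        errs.append(recon_l1(batch, x_hat) * len(batch))
    return float(np.sum(errs) / len(val_items))


def train(train_set, val_healthy_set, net_cfg: NetworkConfig,
          train_cfg: TrainConfig, log_fn=None):
    """Train a VAE on healthy data; returns (model at best epoch, TrainLog).

    ``train_set`` / ``val_healthy_set`` are sequences of healthy volumes
    (rank 3) or are converted to axial slice streams for rank-2 networks.
    """
    if len(train_set) == 0 or len(val_healthy_set) == 0:
        raise TrainingError("training and validation sets must be non-empty")

    rng = np.random.default_rng(train_cfg.seed)
    model = VAE(net_cfg)

    items = [np.asarray(v, dtype=np.float32) for v in train_set]
    val_items = [np.asarray(v, dtype=np.float32) for v in val_healthy_set]
    if train_cfg.subset_fraction < 1.0:
        items = select_subset(items, train_cfg.subset_fraction, train_cfg.seed)
        if len(items) == 0:
            raise TrainingError("subset_fraction selected an empty training set")
    if net_cfg.rank == 2:
        items = make_2d_training_stream(items, rng)
        val_items = make_2d_training_stream(
            val_items, np.random.default_rng(train_cfg.seed + 1)
        )

    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    log = TrainLog()
    best_state, best_val = None, np.inf

    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(items))
        ep_loss, ep_recon, ep_kl, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, len(items), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            inputs, targets = [], []
            for i in idx:
                sample = apply_erasing(items[i], train_cfg.erasing, rng)
                inputs.append(sample.input)
                targets.append(sample.target)
            x_in = np.stack(inputs).astype(np.float32)
            x_tg = np.stack(targets).astype(np.float32)
            losses = model.forward_train(x_in, x_tg, rng,
                                         kl_weight=train_cfg.kl_weight)
            if not np.isfinite(losses["loss"]):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: {losses}"
                )
            model.backward()
            opt.step()
            ep_loss += losses["loss"]
            ep_recon += losses["recon_l1"]
            ep_kl += losses["kl"]
            n_batches += 1
        log.train_loss.append(ep_loss / n_batches)
        log.train_recon.append(ep_recon / n_batches)
        log.train_kl.append(ep_kl / n_batches)

        val_err = _validation_recon(model, val_items, train_cfg.batch_size)
        log.val_recon.append(val_err)
        if val_err < best_val:
            best_val = val_err
            best_state = model.state_dict()
        if log_fn is not None:
            log_fn(epoch=epoch, train_loss=log.train_loss[-1],
                   train_recon=log.train_recon[-1], train_kl=log.train_kl[-1],
                   val_recon=val_err)

    log.selected_epoch = int(np.argmin(log.val_recon))
    model.load_state_dict(best_state)
    return model, log
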