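"""Train a small 3D VAE on healthy phantoms with single-region noise erasing.

Runs at a reduced scale (16^3 phantoms, a few dozen subjects, a handful of
epochs) so it finishes in about a minute on one CPU core.  The epoch with
the lowest reconstruction error on held-out *healthy* volumes is selected —
no lesioned data is ever seen during training.
"""

from brainuad.erasing import ErasingConfig
from brainuad.phantom import PhantomSpec, generate_healthy
from brainuad.trainer import TrainConfig, train
from brainuad.vae import NetworkConfig, save_checkpoint

GRID = 16
volumes = [generate_healthy(PhantomSpec(grid_size=GRID, noise_sigma=0.02,
                                        symmetry_jitter=1.0, seed=i))[0]
           for i in range(40)]
train_set, val_set = volumes[:34], volumes[34:]

net_cfg = NetworkConfig(rank=3, input_extent=GRID, latent_dim=16,
                        stage_channels=(8, 16), seed=0)
train_cfg = TrainConfig(batch_size=8, learning_rate=0.001, max_epochs=6,
                        erasing=ErasingConfig("single", fill="noise"),
                        kl_weight=1.0 / GRID**3, seed=0)


def show(**kw):
    print(f"epoch {kw['epoch']}: train loss {kw['train_loss']:.5f}, "
          f"healthy-val recon l1 {kw['val_recon']:.5f}")


model, log = train(train_set, val_set, net_cfg, train_cfg, log_fn=show)
print(f"\nselected epoch {log.selected_epoch} "
      f"(val recon {log.val_recon[log.selected_epoch]:.5f})")
save_checkpoint("small_vae.npz", model, {"selected_epoch": log.selected_epoch})
print("checkpoint written to small_vae.npz")
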