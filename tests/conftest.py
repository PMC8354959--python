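import numpy as np
import pytest

from brainuad.phantom import LesionSpec, PhantomSpec, generate_healthy, insert_lesions
from brainuad.trainer import TrainConfig, train
from brainuad.vae import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def healthy_phantom_32():
    spec = PhantomSpec(grid_size=32, noise_sigma=0.02, symmetry_jitter=1.0, seed=7)
    return generate_healthy(spec)


@pytest.fixture(scope="session")
def lesioned_phantom_32(healthy_phantom_32):
    vol, mask = healthy_phantom_32
    lspec = LesionSpec(n_lesions=1, radius_range=(2.5, 4.5),
                       intensity_shift=0.4, seed=11)
    lvol, ann = insert_lesions(vol, mask, lspec)
    return lvol, mask, ann


def tiny_net_cfg(rank=3, extent=16, seed=0):
    return NetworkConfig(rank=rank, input_extent=extent, latent_dim=16,
                         stage_channels=(8, 16), seed=seed)


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A small 3D VAE trained briefly on 16^3 phantoms; used by several suites."""
    vols = []
    for i in range(14):
        spec = PhantomSpec(grid_size=16, noise_sigma=0.02, symmetry_jitter=0.5,
                           seed=100 + i)
        vols.append(generate_healthy(spec)[0])
    cfg = TrainConfig(batch_size=8, max_epochs=4, kl_weight=1.0 / 16**3, seed=3)
    model, log = train(vols[:12], vols[12:], tiny_net_cfg(seed=1), cfg)
    return model, log
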