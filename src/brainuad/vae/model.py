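"""Dimension-generic variational autoencoder for normalized brain images.

The same architecture is instantiated at rank 2 (axial slices) or rank 3 (whole
volumes): a stack of stride-2 convolutions halves the spatial extent per stage,
starting with the first convolution, a dense head maps the flattened features to
the Gaussian posterior parameters (mu, logvar), and a mirrored stack of
transposed convolutions reconstructs the input.  The final sigmoid keeps the
output in the normalized intensity range [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn


@dataclass
class NetworkConfig:
    """Architecture description shared by the 2D and 3D variants.

    latent_dim defaults to 128 at rank 2 and 512 at rank 3; stage_channels are
    the encoder feature-map counts per stride-2 stage (the decoder mirrors them).
    """

    rank: int = 3
    input_extent: int = 64
    latent_dim: int | None = None
    stage_channels: tuple[int, ...] = (32, 64, 128, 256)
    kernel_size: int = 4
    activation: str = "leaky_relu"
    output_activation: str = "clip"  # "clip" (bounded linear) or "sigmoid"
    seed: int = 0

    def __post_init__(self):
        if self.rank not in (2, 3):
            raise ValueError(f"rank must be 2 or 3, got {self.rank}")
        if self.latent_dim is None:
            self.latent_dim = 128 if self.rank == 2 else 512
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        n_stages = len(self.stage_channels)
        if self.input_extent % (2**n_stages) != 0:
            raise ValueError(
                f"input_extent {self.input_extent} not divisible by 2^{n_stages}"
            )
        if self.output_activation not in ("clip", "sigmoid"):
            raise ValueError(f"unknown output_activation {self.output_activation!r}")
        if self.kernel_size % 2 != 0 or self.kernel_size < 2:
            raise ValueError(
                "kernel_size must be even (stride-2 stages must halve/double "
                "the extent exactly)"
            )

    @property
    def bottleneck_extent(self) -> int:
        return self.input_extent // (2 ** len(self.stage_channels))

    @property
    def bottleneck_features(self) -> int:
        return self.stage_channels[-1] * self.bottleneck_extent**self.rank


@dataclass
class LatentCode:
    """Per-sample mean and log-variance of the diagonal-Gaussian posterior."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu)
        self.logvar = np.asarray(self.logvar)
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar must have identical shapes")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.logvar))):
            raise ValueError("latent code must be finite")


class VAE:
    """Convolutional VAE; ``rank`` selects 2D (slice) or 3D (volume) operators."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        r, k = cfg.rank, cfg.kernel_size
        pad = (k - 2) // 2

        enc = []
        c_prev = 1
        for c in cfg.stage_channels:
            enc.append(nn.Conv(r, c_prev, c, kernel=k, stride=2, pad=pad, rng=rng))
            enc.append(nn.LeakyReLU())
            c_prev = c
        enc.append(nn.Reshape((cfg.bottleneck_features,)))
        self.encoder = nn.Sequential(enc)
        self.head_mu = nn.Dense(cfg.bottleneck_features, cfg.latent_dim, rng=rng)
        self.head_logvar = nn.Dense(cfg.bottleneck_features, cfg.latent_dim, rng=rng)

        be = cfg.bottleneck_extent
        dec = [
            nn.Dense(cfg.latent_dim, cfg.bottleneck_features, rng=rng),
            nn.LeakyReLU(),
            nn.Reshape((cfg.stage_channels[-1],) + (be,) * r),
        ]
        rev = list(cfg.stage_channels[::-1])
        outs = rev[1:] + [1]
        for c_in, c_out in zip(rev, outs):
            dec.append(
                nn.ConvTranspose(r, c_in, c_out, kernel=k, stride=2, pad=pad, rng=rng)
            )
            if c_out != 1:
                dec.append(nn.LeakyReLU())
        dec.append(nn.Sigmoid() if cfg.output_activation == "sigmoid"
                   else nn.HardClip01())
        self.decoder = nn.Sequential(dec)

    # ------------------------------------------------------------------ API
    def _check_input(self, x):
        x = np.asarray(x, dtype=np.float32)
        expect = (self.cfg.input_extent,) * self.cfg.rank
        if x.ndim == self.cfg.rank:  # single sample without batch/channel axes
            x = x[None, None]
        elif x.ndim == self.cfg.rank + 1:  # batch without channel axis
            x = x[:, None]
        if x.shape[2:] != expect or x.shape[1] != 1:
            raise ValueError(f"expected spatial shape {expect}, got {x.shape[2:]}")
        return x

    def encode(self, x) -> LatentCode:
        x = self._check_input(x)
        h = self.encoder.forward(x)
        return LatentCode(self.head_mu.forward(h), self.head_logvar.forward(h))

    def decode(self, z) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float32))
        if z.shape[1] != self.cfg.latent_dim:
            raise ValueError(
                f"latent dimension {z.shape[1]} != configured {self.cfg.latent_dim}"
            )
        return self.decoder.forward(z)[:, 0]

    def reconstruct(self, x) -> np.ndarray:
        """Deterministic reconstruction from the posterior mean (z = mu)."""
        return self.decode(self.encode(x).mu)

    # --------------------------------------------------------------- training
    def forward_train(self, x_in, x_target, rng, kl_weight=1.0):
        """One erased-input / clean-target pass; returns loss dict and caches."""
        x_in = self._check_input(x_in)
        x_target = self._check_input(x_target)
        h = self.encoder.forward(x_in)
        mu = self.head_mu.forward(h)
        logvar = np.clip(self.head_logvar.forward(h), -10.0, 10.0)
        code = LatentCode(mu, logvar)
        eps = rng.standard_normal(mu.shape).astype(np.float32)
        z = reparameterize(code, eps=eps)
        x_hat = self.decoder.forward(z)
        total, recon, kl = vae_loss(x_target[:, 0], x_hat[:, 0], code, kl_weight)
        self._cache = (x_in, x_target, mu, logvar, eps, z, x_hat, kl_weight)
        return {"loss": total, "recon_l1": recon, "kl": kl}

    def backward(self):
        x_in, x_target, mu, logvar, eps, z, x_hat, kl_weight = self._cache
        b = x_in.shape[0]
        n_el = x_hat[:, 0].size
        dxhat = np.sign(x_hat - x_target) / n_el
        dz = self.decoder.backward(dxhat.astype(np.float32))
        # KL gradients (batch-mean of 0.5 * sum(mu^2 + e^lv - 1 - lv))
        dmu_kl = kl_weight * mu / b
        dlv_kl = kl_weight * 0.5 * (np.exp(logvar) - 1.0) / b
        # reparameterization: z = mu + exp(lv/2) * eps
        dmu = dz + dmu_kl
        dlv = dz * eps * 0.5 * np.exp(0.5 * logvar) + dlv_kl
        dh = self.head_mu.backward(dmu.astype(np.float32))
        dh = dh + self.head_logvar.backward(dlv.astype(np.float32))
        self.encoder.backward(dh)

    def parameters(self):
        entries = []
        for tag, seq in (("enc", self.encoder), ("dec", self.decoder)):
            for key, p, g, n in seq.parameters():
                entries.append((f"{tag}.{key}", p, g, n))
        for tag, layer in (("mu", self.head_mu), ("lv", self.head_logvar)):
            for n in layer.params:
                entries.append((f"{tag}.{n}", layer.params, layer.grads, n))
        return entries

    def n_parameters(self) -> int:
        return sum(int(p[n].size) for _, p, _, n in self.parameters())

    # ------------------------------------------------------------ checkpoints
    def state_dict(self):
        return {key: p[n].copy() for key, p, _, n in self.parameters()}

    def load_state_dict(self, state):
        for key, p, _, n in self.parameters():
            p[n] = np.asarray(state[key], dtype=p[n].dtype).copy()


def reparameterize(code: LatentCode, rng=None, eps=None) -> np.ndarray:
    """Sample z = mu + exp(logvar/2) * eps with eps ~ N(0, I)."""
    if eps is None:
        if rng is None:
            raise ValueError("provide either rng or eps")
        eps = rng.standard_normal(code.mu.shape)
    return code.mu + np.exp(0.5 * code.logvar) * eps


def recon_l1(x_target, x_hat) -> float:
    """Mean absolute difference over all elements (and batch, if present)."""
    x_target = np.asarray(x_target)
    x_hat = np.asarray(x_hat)
    if x_target.shape != x_hat.shape:
        raise ValueError(
            f"shape mismatch: {x_target.shape} vs {x_hat.shape}"
        )
    return float(np.mean(np.abs(x_target.astype(np.float64) - x_hat)))


def kl_term(code: LatentCode) -> float:
    """Closed-form KL(N(mu, diag e^logvar) || N(0, I)), averaged over the batch."""
    mu = np.atleast_2d(code.mu).astype(np.float64)
    lv = np.atleast_2d(code.logvar).astype(np.float64)
    per_sample = 0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv, axis=1)
    return float(np.mean(per_sample))


def vae_loss(x_target, x_hat, code: LatentCode, kl_weight: float = 1.0):
    """Total loss = recon_l1 + kl_weight * kl_term; components returned too."""
    recon = recon_l1(x_target, x_hat)
    kl = kl_term(code)
    return recon + kl_weight * kl, recon, kl


def save_checkpoint(path, model: VAE, extra: dict | None = None):
    """Persist weights + full NetworkConfig (+ optional metadata) to an .npz."""
    cfg_json = json.dumps(asdict(model.cfg))
    meta = json.dumps(extra or {})
    np.savez(path, __config__=cfg_json, __meta__=meta, **model.state_dict())


def load_checkpoint(path) -> tuple[VAE, dict]:
    with np.load(path, allow_pickle=False) as npz:
        cfg_d = json.loads(str(npz["__config__"]))
        meta = json.loads(str(npz["__meta__"]))
        cfg_d["stage_channels"] = tuple(cfg_d["stage_channels"])
        cfg = NetworkConfig(**cfg_d)
        model = VAE(cfg)
        model.load_state_dict({k: npz[k] for k in npz.files if not k.startswith("__")})
    return model, meta
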