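"""DCGAN for 64x64 normalized velocity images, trained on normal flow only.

Generator: a dense projection of the 100-dimensional latent vector to a
4x4 feature map, followed by four fractionally-strided deconvolution blocks
(4 -> 8 -> 16 -> 32 -> 64 px).  Blocks 1-3 use batch normalization + ReLU;
block 4 is a bare deconvolution with a tanh output, so every generated image
lies in [-1, 1].  Discriminator: four strided convolution blocks with
LeakyReLU (batch-normalized from block 2 on), flattened and linearized to a
scalar logit; the sigmoid of the logit is the 'real' probability.  Training
is the standard min-max game

    min_G max_D  E_x[log D(x)] + E_z[log(1 - D(G(z)))]

with the non-saturating generator objective (maximize log D(G(z))) by
default.  Latent vectors are drawn uniformly from [-1, 1]^latent_dim.
Velocity images are single-channel: the flow image is a signed scalar field,
not an RGB rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from hemoflow import nn
from hemoflow.types import ContractError, FlowImage, Label

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    """Adversarial training hyperparameters."""

    epochs: int = 25
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 64
    latent_dim: int = 100
    base_width: int = 32
    n_channels: int = 1
    seed: int = 0
    non_saturating: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ContractError("epochs must be >= 1")
        if not self.learning_rate > 0:
            raise ContractError("learning_rate must be > 0")


def build_generator(cfg: TrainConfig, rng: np.random.Generator) -> nn.Sequential:
    """Latent vector -> 64x64 image in [-1, 1]."""
    w = cfg.base_width
    return nn.Sequential(
        nn.Dense(cfg.latent_dim, 8 * w * 4 * 4, rng),
        nn.Reshape((8 * w, 4, 4)),
        nn.BatchNorm2d(8 * w),
        nn.ReLU(),
        # block 1
        nn.ConvTranspose2d(8 * w, 4 * w, rng),
        nn.BatchNorm2d(4 * w),
        nn.ReLU(),
        # block 2
        nn.ConvTranspose2d(4 * w, 2 * w, rng),
        nn.BatchNorm2d(2 * w),
        nn.ReLU(),
        # block 3
        nn.ConvTranspose2d(2 * w, w, rng),
        nn.BatchNorm2d(w),
        nn.ReLU(),
        # block 4: bare deconvolution + saturating output
        nn.ConvTranspose2d(w, cfg.n_channels, rng),
        nn.Tanh(),
    )


def build_discriminator(cfg: TrainConfig, rng: np.random.Generator) -> nn.Sequential:
    """64x64 image -> scalar logit (sigmoid gives the 'real' probability)."""
    w = cfg.base_width
    return nn.Sequential(
        nn.Conv2d(cfg.n_channels, w, rng),
        nn.LeakyReLU(0.2),
        nn.Conv2d(w, 2 * w, rng),
        nn.BatchNorm2d(2 * w),
        nn.LeakyReLU(0.2),
        nn.Conv2d(2 * w, 4 * w, rng),
        nn.BatchNorm2d(4 * w),
        nn.LeakyReLU(0.2),
        nn.Conv2d(4 * w, 8 * w, rng),
        nn.BatchNorm2d(8 * w),
        nn.LeakyReLU(0.2),
        nn.Flatten(),
        nn.Dense(8 * w * 4 * 4, 1, rng),
    )


@dataclass
class GanModel:
    """Trained generator/discriminator pair plus training metadata."""

    generator: nn.Sequential
    discriminator: nn.Sequential
    config: TrainConfig
    loss_history: dict = field(default_factory=dict)

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    def sample_latent(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Latent prior: uniform on [-1, 1]^latent_dim."""
        return rng.uniform(-1.0, 1.0, size=(n, self.latent_dim)).astype(nn.layers.DTYPE)

    def generate(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        """G(z): (n, latent_dim) -> (n, C, 64, 64) images in [-1, 1]."""
        z = np.atleast_2d(np.asarray(z, dtype=nn.layers.DTYPE))
        if z.shape[1] != self.latent_dim:
            raise ContractError(
                f"latent length {z.shape[1]} != model latent_dim {self.latent_dim}"
            )
        if not np.all(np.isfinite(z)):
            raise ContractError("latent vector must be finite")
        return self.generator.forward(z, train=train)

    def discriminate(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """D(x): returns (probability, logit), both shape (n,)."""
        x = np.asarray(x, dtype=nn.layers.DTYPE)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != 64 or x.shape[3] != 64:
            raise ContractError(f"discriminator expects 64x64 images, got {x.shape}")
        logit = self.discriminator.forward(x, train=train).reshape(-1)
        return _sigmoid(logit), logit

    # -- checkpointing -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": asdict(self.config),
            "loss_history": {k: list(map(float, v)) for k, v in self.loss_history.items()},
        }
        arrays = {f"g.{k}": v for k, v in self.generator.state_dict().items()}
        arrays |= {f"d.{k}": v for k, v in self.discriminator.state_dict().items()}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GanModel":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ContractError(
                    f"unsupported checkpoint format {meta['format_version']}"
                )
            cfg = TrainConfig(**meta["config"])
            rng = np.random.default_rng(0)
            gen = build_generator(cfg, rng)
            disc = build_discriminator(cfg, rng)
            gen.load_state_dict(
                {k[2:]: data[k] for k in data.files if k.startswith("g.")}
            )
            disc.load_state_dict(
                {k[2:]: data[k] for k in data.files if k.startswith("d.")}
            )
            return cls(gen, disc, cfg, loss_history=meta["loss_history"])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _bce_with_logits(logit: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy vs a constant target; returns (loss, dlogit).

    Stable form: softplus(logit) - target * logit, with
    softplus(l) = max(l, 0) + log1p(exp(-|l|)).
    """
    sp = np.maximum(logit, 0.0) + np.log1p(np.exp(-np.abs(logit)))
    loss = float(np.mean(sp - target * logit))
    dlogit = (_sigmoid(logit) - target) / logit.size
    return loss, dlogit


def _as_image_array(dataset, n_channels: int) -> np.ndarray:
    """Stack FlowImages (or raw arrays) into (N, C, 64, 64), checking labels."""
    imgs = []
    for item in dataset:
        if isinstance(item, FlowImage):
            if item.label is not Label.NORMAL:
                raise ContractError(
                    f"training contamination: image {item.provenance!r} has "
                    f"label {item.label.value!r}, only 'normal' is allowed"
                )
            imgs.append(item.pixels)
        else:
            imgs.append(np.asarray(item, dtype=float))
    if not imgs:
        raise ContractError("empty training dataset")
    arr = np.stack(imgs).astype(nn.layers.DTYPE)
    if arr.ndim == 3:
        arr = arr[:, None]
    if arr.shape[1] != n_channels:
        raise ContractError(f"expected {n_channels}-channel images, got {arr.shape}")
    return arr


def train_gan(dataset, cfg: TrainConfig, callback=None) -> GanModel:
    """Adversarial training on normal flow images only.

    Alternates one discriminator update (real batch vs generated batch) with
    one generator update per minibatch.  Any image labelled other than
    ``normal`` is refused outright: the anomaly detector's premise is that
    the generator never sees a hemorrhage.  Per-epoch mean losses (and the
    value of the adversarial objective V) are recorded in
    ``model.loss_history``; the whole run is a pure function of
    (dataset, cfg).
    """
    x_all = _as_image_array(dataset, cfg.n_channels)
    n = x_all.shape[0]
    if n < cfg.batch_size:
        raise ContractError(
            f"dataset size {n} is smaller than batch_size {cfg.batch_size}"
        )
    ss = np.random.SeedSequence([cfg.seed, 0x6A4])
    init_rng, train_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    gen = build_generator(cfg, init_rng)
    disc = build_discriminator(cfg, init_rng)
    model = GanModel(gen, disc, cfg)
    opt_g = nn.Adam(gen, lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2)
    opt_d = nn.Adam(disc, lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2)

    history = {"d_loss": [], "g_loss": [], "v_value": []}
    for epoch in range(cfg.epochs):
        order = train_rng.permutation(n)
        d_losses, g_losses, v_values = [], [], []
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            x_real = x_all[order[start : start + cfg.batch_size]]
            bs = x_real.shape[0]

            # --- discriminator step: max log D(x) + log(1 - D(G(z)))
            z = model.sample_latent(bs, train_rng)
            x_fake = gen.forward(z, train=True)
            logit_real = disc.forward(x_real, train=True).reshape(-1)
            loss_real, dlr = _bce_with_logits(logit_real, 1.0)
            disc.backward(dlr.reshape(-1, 1))
            grads_real = {
                full: layer.grads[name].copy()
                for full, layer, name, _ in disc.named_params()
            }
            logit_fake = disc.forward(x_fake, train=True).reshape(-1)
            loss_fake, dlf = _bce_with_logits(logit_fake, 0.0)
            disc.backward(dlf.reshape(-1, 1))
            for full, layer, name, _ in disc.named_params():
                layer.grads[name] = layer.grads[name] + grads_real[full]
            opt_d.step()
            d_loss = loss_real + loss_fake
            # V(G, D) = E[log D(x)] + E[log(1 - D(G(z)))] = -(d_loss)
            v_values.append(-d_loss)
            d_losses.append(d_loss)

            # --- generator step
            z = model.sample_latent(bs, train_rng)
            x_fake = gen.forward(z, train=True)
            logit_fake = disc.forward(x_fake, train=True).reshape(-1)
            if cfg.non_saturating:
                g_loss, dlogit = _bce_with_logits(logit_fake, 1.0)
            else:
                # literal min log(1 - D(G(z))): loss = -BCE(logit, 0)
                loss0, d0 = _bce_with_logits(logit_fake, 0.0)
                g_loss, dlogit = -loss0, -d0
            dx_fake = disc.backward(dlogit.reshape(-1, 1))
            gen.backward(dx_fake)
            opt_g.step()
            g_losses.append(g_loss)

        history["d_loss"].append(float(np.mean(d_losses)))
        history["g_loss"].append(float(np.mean(g_losses)))
        history["v_value"].append(float(np.mean(v_values)))
        if callback is not None:
            callback(epoch, history)
    model.loss_history = history
    return model
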