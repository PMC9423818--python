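"""Iterative latent-space mapping: anomaly score and residual localization.

A query image x is mapped onto the generator's learned manifold of normal
flow by gradient descent in latent space with all network weights frozen:
starting from a random z, repeat for phi steps

    L_R(z) = sum |x - G(z)|                (residual loss, normalized)
    L_D(z) = softplus(-D_logit(G(z)))      (discrimination loss, BCE vs 'real')
    L(z)   = (1 - gamma) L_R + gamma L_D
    z     <- z - step_size * dL/dz

The anomaly score A = (1 - gamma) L_R + gamma L_D at the final evaluated
step, clamped to [0, 1]; the residual map |x - G(z_phi)| localizes what the
normal-flow manifold cannot explain.  The residual loss is normalized by
(pixel count x dynamic range 2) so identical images score 0 and maximally
opposed images score 1, which keeps A on the stated [0, 1] scale; the raw
absolute sum remains available for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from hemoflow.gan import GanModel, _sigmoid
from hemoflow.preprocess import otsu_threshold
from hemoflow.nn import layers as _nn_layers
from hemoflow.types import AnomalyResult, ContractError, FlowImage


def nn_dtype():
    """Working dtype of the network stack (single precision by default)."""
    return _nn_layers.DTYPE

logger = logging.getLogger(__name__)


@dataclass
class MapperConfig:
    """Latent-inversion hyperparameters.

    ``n_steps`` is the number of backpropagation steps (2000 in the full
    protocol; smaller values trade accuracy for speed), ``gamma`` weights the
    discrimination loss against the residual loss (0.1 in the protocol),
    ``alpha`` is the discrimination target ('real' = 1).
    """

    n_steps: int = 2000
    gamma: float = 0.1
    step_size: float = 0.05
    momentum: float = 0.9
    alpha: float = 1.0
    seed: int = 0
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ContractError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.n_steps < 1:
            raise ContractError("n_steps must be >= 1")
        if self.n_restarts < 1:
            raise ContractError("n_restarts must be >= 1")


def residual_loss(x: np.ndarray, gz: np.ndarray, normalized: bool = True) -> float:
    """Visual dissimilarity sum |x - G(z)|, optionally normalized to [0, 1].

    Normalization divides the raw absolute sum by (pixel count x 2), the
    largest possible disagreement between two images in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    gz = np.asarray(gz, dtype=float)
    if x.shape != gz.shape:
        raise ContractError(f"shape mismatch: {x.shape} vs {gz.shape}")
    raw = float(np.sum(np.abs(x - gz)))
    if not normalized:
        return raw
    return raw / (x.size * 2.0)


def discrimination_loss(x_gen: np.ndarray, model: GanModel, alpha: float = 1.0) -> float:
    """Sigmoid cross-entropy of the discriminator logit against target alpha.

    For alpha = 1 this is softplus(-logit): zero when the discriminator is
    certain the reconstruction is real, large when it is certain it is fake.
    """
    _, logit = model.discriminate(x_gen)
    return float(np.mean(_softplus_bce(logit, alpha)))


def _softplus_bce(logit: np.ndarray, target: float) -> np.ndarray:
    # BCE(sigmoid(l), t) = softplus(l) - t*l, in overflow-safe form
    return np.maximum(logit, 0.0) + np.log1p(np.exp(-np.abs(logit))) - target * logit


def total_loss(lr: float, ld: float, gamma: float) -> float:
    """Weighted combination (1 - gamma) * L_R + gamma * L_D."""
    if not (0.0 <= gamma <= 1.0):
        raise ContractError(f"gamma must lie in [0, 1], got {gamma}")
    return (1.0 - gamma) * lr + gamma * ld


def map_to_latent(
    x: FlowImage | np.ndarray,
    model: GanModel,
    cfg: MapperConfig,
    z_init: np.ndarray | None = None,
) -> AnomalyResult:
    """Invert one query image through the frozen generator (Algorithm above).

    Each restart samples z from the latent prior (or uses ``z_init``, mainly
    for fixed-point tests), runs ``n_steps`` loss evaluations each followed
    by a gradient step on z alone, and reports the losses of the final
    evaluation.  With ``n_restarts > 1`` the restart with the smallest final
    total loss wins.  Generator and discriminator weights are asserted
    bit-identical before and after.
    """
    pixels = x.pixels if isinstance(x, FlowImage) else np.asarray(x, dtype=float)
    if pixels.ndim != 2:
        raise ContractError("query image must be a 2-D raster")
    target = pixels[None, None].astype(nn_dtype())
    gen, disc = model.generator, model.discriminator
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x3A9]))

    w_before = gen.state_dict() | {
        "d_" + k: v for k, v in disc.state_dict().items()
    }

    # restarts descend together as one batch: rows are independent because
    # every layer (batchnorm in eval mode included) acts per-sample
    n_px = float(target.size)
    z = model.sample_latent(cfg.n_restarts, rng)
    if z_init is not None:
        z[0] = np.asarray(z_init, dtype=nn_dtype()).reshape(-1)
    vel = np.zeros_like(z)
    trajectory = np.empty((cfg.n_steps, cfg.n_restarts))
    lr_fin = ld_fin = raw_fin = None
    gz = None
    for step in range(cfg.n_steps):
        gz = gen.forward(z, train=False)
        diff = gz - target
        raw = np.abs(diff).sum(axis=(1, 2, 3)).astype(float)
        lr_val = raw / (n_px * 2.0)
        _, logit = model.discriminate(gz)
        ld_val = _softplus_bce(logit.astype(float), cfg.alpha)
        loss = (1.0 - cfg.gamma) * lr_val + cfg.gamma * ld_val
        if not np.all(np.isfinite(loss)):
            raise ContractError(
                "non-finite total loss during latent descent at step "
                f"{step}; trajectory so far: {trajectory[:step].tolist()}"
            )
        trajectory[step] = loss
        lr_fin, ld_fin, raw_fin = lr_val, ld_val, raw

        # d(total)/d(G(z)); residual part is the L1 subgradient
        dgz = (1.0 - cfg.gamma) * np.sign(diff) / (n_px * 2.0)
        if cfg.gamma > 0.0:
            dlogit = _sigmoid(logit) - cfg.alpha
            dgz = dgz + cfg.gamma * disc.backward(dlogit.reshape(-1, 1))
        dz = gen.backward(dgz)
        vel = cfg.momentum * vel - cfg.step_size * dz
        z = z + vel

    win = int(np.argmin(trajectory[-1]))
    best = AnomalyResult(
        reconstruction=gz[win, 0].copy(),
        residual=np.abs(pixels - gz[win, 0]),
        score=float(
            np.clip(total_loss(lr_fin[win], ld_fin[win], cfg.gamma), 0.0, 1.0)
        ),
        loss_trajectory=trajectory[:, win].copy(),
        final_z=z[win].copy(),
        residual_loss=float(lr_fin[win]),
        discrimination_loss=float(ld_fin[win]),
        raw_residual_sum=float(raw_fin[win]),
        provenance=x.provenance if isinstance(x, FlowImage) else "",
    )

    w_after = gen.state_dict() | {"d_" + k: v for k, v in disc.state_dict().items()}
    for k in w_before:
        if not np.array_equal(w_before[k], w_after[k]):
            raise ContractError(f"frozen-weights contract violated at {k}")
    return best


def binarize_residual(
    residuals: list[np.ndarray], rule: str = "otsu", percentile: float = 95.0,
    n_bins: int = 256,
) -> tuple[list[np.ndarray], float]:
    """Threshold a set of residual maps at one global value.

    The threshold is determined from the pooled histogram of all residual
    pixels — Otsu's between-class-variance maximizer by default, or a fixed
    percentile.  Returns per-image binary maps (True = hemorrhage candidate)
    and the chosen threshold.
    """
    if len(residuals) == 0:
        raise ContractError("need at least one residual map")
    pooled = np.concatenate([np.asarray(r, dtype=float).ravel() for r in residuals])
    if np.any(pooled < 0):
        raise ContractError("residual maps must be non-negative")
    if np.all(pooled == 0):
        logger.warning("all residuals are zero; threshold set to 0, maps empty")
        return [np.zeros_like(np.asarray(r), dtype=bool) for r in residuals], 0.0
    if rule == "otsu":
        if pooled.min() == pooled.max():
            thresh = float(pooled.max())
            return [np.asarray(r) > thresh for r in residuals], thresh
        thresh = otsu_threshold(pooled, n_bins=n_bins)
    elif rule == "percentile":
        thresh = float(np.percentile(pooled, percentile))
    else:
        raise ContractError(f"unknown threshold rule {rule!r}")
    return [np.asarray(r, dtype=float) > thresh for r in residuals], thresh


def score_frame_sequence(
    binary_maps: list[np.ndarray], persistence_fraction: float = 0.8
) -> str:
    """Sequence-level call from per-frame binarized residuals.

    Declares ``'hemorrhage'`` when the fraction of frames with any candidate
    pixel reaches ``persistence_fraction``: a real bleed leaves residual
    regions in almost every frame, while sporadic false positives do not.
    """
    if len(binary_maps) == 0:
        raise ContractError("need at least one frame")
    frac = float(np.mean([bool(np.any(m)) for m in binary_maps]))
    return "hemorrhage" if frac >= persistence_fraction else "no-hemorrhage"
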