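"""Shared fixtures: small synthetic datasets and a tiny trained GAN.

Everything is generated at test time from fixed seeds; the heavier trained
model is session-scoped so mapper/metrics tests share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from hemoflow.gan import TrainConfig, train_gan
from hemoflow.synth import SynthConfig, make_dataset


@pytest.fixture(scope="session")
def synth_cfg() -> SynthConfig:
    return SynthConfig(seed=123)


@pytest.fixture(scope="session")
def small_dataset(synth_cfg):
    """60 normal + 20 hemorrhage preprocessed images with truth masks."""
    return make_dataset(synth_cfg, 60, 20)


@pytest.fixture(scope="session")
def tiny_model(small_dataset):
    """A small DCGAN trained briefly on normal images (shared across tests)."""
    images, _, _ = small_dataset
    normals = [img for img in images if img.label.value == "normal"]
    cfg = TrainConfig(epochs=3, batch_size=20, base_width=8, seed=11)
    return train_gan(normals, cfg)


def otsu_exhaustive(values: np.ndarray, n_bins: int = 256) -> float:
    """Independent Otsu oracle: brute-force search over all histogram splits.

    Returns the threshold (center of the last below-class bin) maximizing the
    between-class variance w0 * w1 * (mu0 - mu1)^2, evaluated in exact
    rational arithmetic over bin indices so ties are broken deterministically
    (first maximizing split), with per-split sums recomputed from scratch.
    """
    from fractions import Fraction

    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=n_bins)
    counts = [int(c) for c in hist]
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_thr = None, None
    for split in range(1, n_bins):
        w0, w1 = sum(counts[:split]), sum(counts[split:])
        if w0 == 0 or w1 == 0:
            continue
        mu0 = Fraction(sum(i * c for i, c in enumerate(counts[:split])), w0)
        mu1 = Fraction(
            sum((split + i) * c for i, c in enumerate(counts[split:])), w1
        )
        var = w0 * w1 * (mu0 - mu1) ** 2
        if best_var is None or var > best_var:
            best_var, best_thr = var, centers[split - 1]
    return float(best_thr)


def auc_pairwise(neg: np.ndarray, pos: np.ndarray) -> float:
    """Independent AUC oracle: P(pos > neg) + 0.5 P(pos = neg) over all pairs."""
    neg = np.asarray(neg, dtype=float)[:, None]
    pos = np.asarray(pos, dtype=float)[None, :]
    return float(np.mean((pos > neg) + 0.5 * (pos == neg)))


def upcast_net(net) -> None:
    """Promote a network's parameters to float64 for numeric gradient checks."""
    from hemoflow.nn.layers import BatchNorm2d

    for _, layer, name, p in net.named_params():
        layer.params[name] = p.astype(np.float64)
    for layer in net.layers:
        if isinstance(layer, BatchNorm2d):
            layer.running_mean = layer.running_mean.astype(np.float64)
            layer.running_var = layer.running_var.astype(np.float64)
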