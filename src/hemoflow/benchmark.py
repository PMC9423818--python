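"""End-to-end synthetic benchmark: the detection experiment in miniature.

Trains the DCGAN on synthetic normal flow images only, maps held-out normal
and hemorrhage images into latent space, and evaluates the separation of the
anomaly-score distributions (AUC, medians, rank test) plus pixel-level
localization of the binarized residuals against the phantom's ground-truth
jet masks.  Used by both the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from hemoflow.gan import TrainConfig, train_gan
from hemoflow.mapper import MapperConfig, binarize_residual, map_to_latent
from hemoflow.metrics import compare_score_groups, roc_from_scores, sens_spec_at
from hemoflow.synth import SynthConfig, make_dataset
from hemoflow.types import Label


@dataclass
class BenchmarkResult:
    auc: float
    median_normal: float
    median_hemorrhage: float
    mean_normal: float
    mean_hemorrhage: float
    p_adjusted: float
    sensitivity: float
    specificity: float
    residual_threshold: float
    localization_overlap: float
    residual_inside_jet: float
    residual_outside_jet: float
    n_train: int
    n_test_per_class: int
    scores_normal: np.ndarray = field(repr=False, default=None)
    scores_hemorrhage: np.ndarray = field(repr=False, default=None)


def run_benchmark(
    seed: int = 1,
    n_train: int = 500,
    epochs: int = 25,
    n_test_per_class: int = 50,
    n_steps: int = 200,
    gamma: float = 0.1,
    jet_alias_prob: float = 0.5,
    base_width: int = 16,
    batch_size: int = 16,
    n_restarts: int = 1,
) -> BenchmarkResult:
    """Run the scaled-down end-to-end experiment and return its metrics.

    All randomness derives from ``seed``.  Training data and held-out query
    data come from phantoms with distinct seeds, so no query image is ever
    seen in training.  The miniature uses batch size 16 so its number of
    optimizer updates (~780) approximates the full-size protocol's (~1300
    with thousands of images at batch 64); at batch 64 a 500-image run gets
    only ~175 updates and the generator underfits.
    """
    ss = np.random.SeedSequence([int(seed), 0xBEEF])
    seeds = [int(s % (2**31)) for s in ss.generate_state(4)]

    train_cfg_synth = SynthConfig(seed=seeds[0], jet_alias_prob=jet_alias_prob)
    train_imgs, _, _ = make_dataset(train_cfg_synth, n_train, 0)

    gan_cfg = TrainConfig(
        epochs=epochs,
        learning_rate=2e-4,
        batch_size=batch_size,
        latent_dim=100,
        base_width=base_width,
        seed=seeds[1],
    )
    model = train_gan(train_imgs, gan_cfg)

    test_cfg_synth = SynthConfig(seed=seeds[2], jet_alias_prob=jet_alias_prob)
    test_imgs, _, truths = make_dataset(
        test_cfg_synth, n_test_per_class, n_test_per_class
    )

    mcfg = MapperConfig(
        n_steps=n_steps, gamma=gamma, seed=seeds[3], n_restarts=n_restarts
    )
    results = [map_to_latent(img, model, mcfg) for img in test_imgs]
    scores = np.array([r.score for r in results])
    labels = np.array([img.label is Label.HEMORRHAGE for img in test_imgs])
    neg, pos = scores[~labels], scores[labels]

    roc = roc_from_scores(neg, pos)
    thr = roc.youden_threshold()
    sens, spec = sens_spec_at(neg, pos, thr)
    comps = compare_score_groups({"T0": neg, "T1": pos}, "T0")
    p_adj = next(c.p_adjusted for c in comps if c.label == "T1")

    binary_maps, res_thr = binarize_residual([r.residual for r in results])
    overlap = _localization_overlap(binary_maps, truths, labels)
    inside, outside = _residual_contrast(results, truths, labels)

    return BenchmarkResult(
        auc=roc.auc,
        median_normal=float(np.median(neg)),
        median_hemorrhage=float(np.median(pos)),
        mean_normal=float(np.mean(neg)),
        mean_hemorrhage=float(np.mean(pos)),
        p_adjusted=float(p_adj),
        sensitivity=sens,
        specificity=spec,
        residual_threshold=float(res_thr),
        localization_overlap=overlap,
        residual_inside_jet=inside,
        residual_outside_jet=outside,
        n_train=n_train,
        n_test_per_class=n_test_per_class,
        scores_normal=neg,
        scores_hemorrhage=pos,
    )


def _localization_overlap(binary_maps, truths, labels) -> float:
    """Fraction of hemorrhage-candidate pixels inside the dilated truth mask,
    pooled over hemorrhage queries."""
    hits = total = 0
    for bmap, truth, is_hem in zip(binary_maps, truths, labels):
        if not is_hem or truth is None:
            continue
        dilated = ndimage.binary_dilation(truth, iterations=3)
        hits += int(np.sum(bmap & dilated))
        total += int(np.sum(bmap))
    return hits / total if total else float("nan")


def _residual_contrast(results, truths, labels) -> tuple[float, float]:
    """Mean residual inside vs outside the dilated jet, hemorrhage queries."""
    ins, outs = [], []
    for res, truth, is_hem in zip(results, truths, labels):
        if not is_hem or truth is None or not truth.any():
            continue
        dilated = ndimage.binary_dilation(truth, iterations=3)
        ins.append(float(res.residual[dilated].mean()))
        outs.append(float(res.residual[~dilated].mean()))
    if not ins:
        return float("nan"), float("nan")
    return float(np.mean(ins)), float(np.mean(outs))
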