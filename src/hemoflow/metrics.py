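"""Detector evaluation: ROC/AUC, sensitivity/specificity, score comparisons.

Mirrors the evaluation protocol of the anomaly detector: anomaly scores (or
residual statistics) from a normal group and one or more hemorrhage groups
are swept over thresholds to build ROC curves; a single operating point
gives sensitivity/specificity; per-timepoint score distributions are
compared to baseline with a rank-based two-sample test, Bonferroni-corrected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from hemoflow.types import ContractError

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    """Threshold sweep with true/false positive rates and trapezoidal AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def youden_threshold(self) -> float:
        """Operating threshold maximizing Youden's J = TPR - FPR."""
        j = self.tpr - self.fpr
        return float(self.thresholds[int(np.argmax(j))])


@dataclass
class ScoreDistributionSummary:
    """Per-group score statistics and the comparison against baseline."""

    label: str
    n: int
    mean: float
    sd: float
    median: float
    p_raw: float = field(default=np.nan)
    p_adjusted: float = field(default=np.nan)


def roc_from_scores(neg_scores, pos_scores) -> RocCurve:
    """ROC over all distinct score thresholds; positives score higher.

    The AUC is the trapezoidal integral of TPR over FPR, which equals the
    pairwise probability P(pos > neg) + 0.5 P(pos = neg) (ties counted half).
    """
    neg = np.asarray(neg_scores, dtype=float).ravel()
    pos = np.asarray(pos_scores, dtype=float).ravel()
    if neg.size == 0 or pos.size == 0:
        raise ContractError("both score groups must be non-empty")
    y = np.concatenate([np.zeros(neg.size), np.ones(pos.size)])
    s = np.concatenate([neg, pos])
    fpr, tpr, thresholds = skm.roc_curve(y, s, drop_intermediate=False)
    return RocCurve(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(skm.auc(fpr, tpr))
    )


def sens_spec_at(neg_scores, pos_scores, threshold: float) -> tuple[float, float]:
    """Sensitivity = P(pos >= t), specificity = P(neg < t) at threshold t."""
    neg = np.asarray(neg_scores, dtype=float).ravel()
    pos = np.asarray(pos_scores, dtype=float).ravel()
    if neg.size == 0 or pos.size == 0:
        raise ContractError("both score groups must be non-empty")
    sensitivity = float(np.mean(pos >= threshold))
    specificity = float(np.mean(neg < threshold))
    return sensitivity, specificity


def compare_score_groups(
    groups: dict[str, np.ndarray], baseline_label: str
) -> list[ScoreDistributionSummary]:
    """Each non-baseline group vs. baseline by Mann-Whitney U, Bonferroni.

    Raw two-sided p-values are multiplied by the number of comparisons and
    capped at 1.  Groups with fewer than 2 scores are excluded with a
    warning.  The baseline's own row carries no p-values.
    """
    if baseline_label not in groups:
        raise ContractError(f"baseline group {baseline_label!r} missing")
    if len(groups) < 2:
        raise ContractError("need at least two groups to compare")
    usable = {}
    for label, scores in groups.items():
        scores = np.asarray(scores, dtype=float).ravel()
        if scores.size < 2:
            logger.warning("group %r has < 2 scores; excluded", label)
            continue
        usable[label] = scores
    if baseline_label not in usable:
        raise ContractError("baseline group too small to compare against")
    base = usable[baseline_label]
    n_comparisons = max(len(usable) - 1, 1)
    out = []
    for label, scores in usable.items():
        summary = ScoreDistributionSummary(
            label=label,
            n=scores.size,
            mean=float(np.mean(scores)),
            sd=float(np.std(scores, ddof=1)),
            median=float(np.median(scores)),
        )
        if label != baseline_label:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # all-tied degenerate groups
                res = stats.mannwhitneyu(scores, base, alternative="two-sided")
            summary.p_raw = float(res.pvalue)
            summary.p_adjusted = float(min(res.pvalue * n_comparisons, 1.0))
        out.append(summary)
    return out


def per_timepoint_report(
    manifest: pd.DataFrame,
    scores: dict[str, float],
    baseline_timepoint: str = "T0",
    plot_path: str | None = None,
) -> pd.DataFrame:
    """One ROC row per anomalous timepoint vs. the normal pool, plus pooled.

    ``manifest`` must carry columns id/label/timepoint; ``scores`` maps image
    id -> anomaly score.  Rows report AUC, Youden-threshold sensitivity and
    specificity, and group size.  Timepoints with no scored images are
    omitted with a warning.  ``plot_path``, if given, receives a ROC figure.
    """
    df = manifest[manifest["id"].isin(scores)].copy()
    df["score"] = df["id"].map(scores)
    neg = df.loc[df["label"] == "normal", "score"].to_numpy()
    if neg.size == 0:
        raise ContractError("no scored normal images in the manifest")
    rows = []
    curves: dict[str, RocCurve] = {}
    anomalous = df[df["label"] != "normal"]
    for tp, grp in anomalous.groupby("timepoint", sort=True):
        pos = grp["score"].to_numpy()
        if pos.size == 0:
            logger.warning("timepoint %r has no scored images; omitted", tp)
            continue
        roc = roc_from_scores(neg, pos)
        thr = roc.youden_threshold()
        sens, spec = sens_spec_at(neg, pos, thr)
        curves[str(tp)] = roc
        rows.append(
            dict(timepoint=str(tp), n_pos=pos.size, n_neg=neg.size, auc=roc.auc,
                 threshold=thr, sensitivity=sens, specificity=spec)
        )
    pos_all = anomalous["score"].to_numpy()
    if pos_all.size:
        roc = roc_from_scores(neg, pos_all)
        thr = roc.youden_threshold()
        sens, spec = sens_spec_at(neg, pos_all, thr)
        curves["pooled"] = roc
        rows.append(
            dict(timepoint="pooled", n_pos=pos_all.size, n_neg=neg.size,
                 auc=roc.auc, threshold=thr, sensitivity=sens, specificity=spec)
        )
    report = pd.DataFrame.from_records(rows)
    if plot_path is not None and curves:
        _plot_rocs(curves, plot_path)
    return report


def _plot_rocs(curves: dict[str, RocCurve], path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in curves.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUC={roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title("Hemorrhage detection ROC")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
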