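"""Evaluation metrics: masked cross-entropy, pooled Dice, one-vs-all AUC.

Per-class confusion counts are *micro-pooled*: pixel counts are accumulated
across every holdout image before any ratio is formed, so the metric for N
images equals the metric for their concatenation. Pixels whose ground truth
is the avoid class are excluded everywhere. The Sørensen-Dice coefficient for
class c is

    dice_c = 2 TP_c / (2 TP_c + FP_c + FN_c)

and a class with TP + FP + FN = 0 (absent from both truth and prediction) is
flagged undefined rather than scored zero. One-vs-all ROC AUC treats each
class's predicted probability as the score against all other classes pooled
as negatives; the value equals the probability that a random positive pixel
outranks a random negative one (ties counting one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .legend import ClassLegend, LabelMap

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "masked_cross_entropy",
    "accumulate_confusion",
    "dice_per_class",
    "roc_auc_one_vs_all",
    "smooth_loss_curve",
    "build_report",
]

PROB_EPS = 1e-12


class MetricError(ValueError):
    pass


def masked_cross_entropy(probabilities: np.ndarray, labels, avoid_index: int) -> float:
    """Mean of -log p(true class) over non-avoid pixels.

    ``probabilities`` is (C, H, W) and normalized per pixel; avoid-class
    pixels contribute nothing (the loss is invariant to their predictions).
    """
    labels = labels.indices if isinstance(labels, LabelMap) else np.asarray(labels)
    if probabilities.shape[1:] != labels.shape:
        raise MetricError(
            f"probabilities {probabilities.shape[1:]} vs labels {labels.shape}"
        )
    mask = labels != avoid_index
    n = int(mask.sum())
    if n == 0:
        raise MetricError("all pixels are avoid-class: loss undefined")
    safe = np.where(mask, labels, 0)
    p_true = np.take_along_axis(probabilities, safe[None], axis=0)[0][mask]
    if (p_true <= 0).any():
        warnings.warn("zero probability at a true class; clamping")
        p_true = np.maximum(p_true, PROB_EPS)
    return float(-np.log(p_true).mean())


@dataclass
class ConfusionCounts:
    """Pooled per-class TP/FP/FN/TN pixel counts over evaluated (non-avoid) pixels."""

    n_classes: int
    tp: np.ndarray = field(default=None)
    fp: np.ndarray = field(default=None)
    fn: np.ndarray = field(default=None)
    tn: np.ndarray = field(default=None)
    n_evaluated_pixels: int = 0

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.n_classes, dtype=np.int64))


def accumulate_confusion(
    pred, truth, legend: ClassLegend, running: ConfusionCounts | None = None
) -> ConfusionCounts:
    """Add one image's pixel counts to the running pooled confusion.

    Truth pixels of the avoid class are skipped entirely; predictions may not
    contain the avoid class.
    """
    pred = pred.indices if isinstance(pred, LabelMap) else np.asarray(pred)
    truth = truth.indices if isinstance(truth, LabelMap) else np.asarray(truth)
    if pred.shape != truth.shape:
        raise MetricError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    c = legend.n_classes
    if running is None:
        running = ConfusionCounts(n_classes=c)
    mask = truth != legend.avoid_index
    p = pred[mask]
    t = truth[mask]
    n = int(mask.sum())
    joint = np.bincount(t.astype(np.int64) * c + p.astype(np.int64), minlength=c * c).reshape(c, c)
    tp = np.diag(joint)
    fn = joint.sum(axis=1) - tp
    fp = joint.sum(axis=0) - tp
    running.tp += tp
    running.fn += fn
    running.fp += fp
    running.tn += n - tp - fn - fp
    running.n_evaluated_pixels += n
    return running


def dice_per_class(counts: ConfusionCounts):
    """Dice per class from pooled counts; returns (dice dict, undefined set)."""
    dice = {}
    undefined = set()
    for c in range(counts.n_classes):
        denom = 2 * counts.tp[c] + counts.fp[c] + counts.fn[c]
        if denom == 0:
            undefined.add(c)
        else:
            dice[c] = float(2 * counts.tp[c] / denom)
    return dice, undefined


def roc_auc_one_vs_all(scores: np.ndarray, truth: np.ndarray):
    """AUC for one class's scores against all others; None if truth is single-class."""
    truth = np.asarray(truth).astype(bool).ravel()
    scores = np.asarray(scores).ravel()
    if truth.all() or not truth.any():
        return None
    return float(roc_auc_score(truth, scores))


def smooth_loss_curve(series, window: int = 3):
    """Centered moving average, window truncated at the edges; same length out."""
    series = np.asarray(series, dtype=np.float64)
    if series.size == 0:
        raise MetricError("empty loss series")
    if window < 1:
        raise MetricError("window must be >= 1")
    kernel = np.ones(window)
    num = np.convolve(series, kernel, mode="same")
    den = np.convolve(np.ones_like(series), kernel, mode="same")
    return num / den


@dataclass
class MetricsReport:
    """Holdout evaluation of one classifier version (micro-pooled)."""

    version_tag: str
    dice: dict  # class name -> dice
    auc: dict  # class name -> auc (classes with both polarities present)
    mean_dice: float
    counts: ConfusionCounts
    classes_absent: set = field(default_factory=set)
    loss_curves: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {name: {"dice": d, "auc": self.auc.get(name)} for name, d in self.dice.items()}
        df = pd.DataFrame(rows).T
        df.loc["Average"] = [self.mean_dice, np.nan]
        return df

    def to_dict(self) -> dict:
        return {
            "version_tag": self.version_tag,
            "dice": self.dice,
            "auc": self.auc,
            "mean_dice": self.mean_dice,
            "classes_absent": sorted(self.classes_absent),
        }


def build_report(
    holdout: list,
    model,
    stats,
    legend: ClassLegend,
    version_tag: str | None = None,
) -> MetricsReport:
    """Evaluate a trained model on the holdout set.

    Pools confusion counts over every holdout image, computes per-class Dice
    and one-vs-all AUC for classes present in the ground truth, and the
    unweighted mean Dice over defined classes. ``model`` may also be a plain
    callable ``sample -> (n_classes, H, W) probabilities`` (e.g. a reference
    predictor in a test).
    """
    if not holdout:
        raise MetricError("empty holdout set")
    if callable(model):
        predict = lambda s: model(s)  # noqa: E731
    else:
        from .unet import predict_proba  # local import to avoid a cycle

        predict = lambda s: predict_proba(model, s, stats)  # noqa: E731
    counts = ConfusionCounts(n_classes=legend.n_classes)
    all_scores = []
    all_truth = []
    for s in holdout:
        probs = predict(s)
        pred = probs.argmax(axis=0)
        counts = accumulate_confusion(pred, s.labels, legend, counts)
        mask = s.labels.indices != legend.avoid_index
        all_scores.append(probs[:, mask])
        all_truth.append(s.labels.indices[mask])
    scores = np.concatenate(all_scores, axis=1)
    truth = np.concatenate(all_truth)

    dice_idx, undefined = dice_per_class(counts)
    present = set(np.unique(truth).tolist())
    dice = {legend.name_of(c): d for c, d in dice_idx.items() if c in present}
    auc = {}
    for c in sorted(present):
        a = roc_auc_one_vs_all(scores[c], truth == c)
        if a is not None:
            auc[legend.name_of(c)] = a
    mean_dice = float(np.mean(list(dice.values()))) if dice else float("nan")
    absent = {legend.name_of(c) for c in range(legend.n_classes) if c not in present}
    return MetricsReport(
        version_tag=version_tag or getattr(model, "version_tag", "C?"),
        dice=dice,
        auc=auc,
        mean_dice=mean_dice,
        counts=counts,
        classes_absent=absent,
    )


def report_table(reports: list) -> pd.DataFrame:
    """Class x version table of Dice values with an Average row."""
    cols = {}
    for r in reports:
        col = dict(r.dice)
        col["Average"] = r.mean_dice
        cols[r.version_tag] = col
    return pd.DataFrame(cols)
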