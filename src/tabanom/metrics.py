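"""Evaluation metrics for unsupervised defect detection.

Image-level: AUROC (threshold-free ranking quality), average precision
(precision integrated over recall), and best F1 over all score thresholds.
Region-level: PRO, the mean over 8-connected ground-truth components of the
fraction of each component recovered by the binarized prediction,

    PRO = (1/N) * sum_n |P ∩ G_n| / |G_n|,

at a fixed threshold; ``aupro`` additionally integrates the per-region
overlap over the false-positive-rate axis up to a limit (0.3 by default)
and normalises, the convention used for cross-paper comparability.

Ranking metrics delegate to scikit-learn; PRO/AUPRO are computed here with
scipy connected-component labelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

__all__ = [
    "MetricsReport", "auroc", "average_precision", "f1_at", "best_f1",
    "pro", "aupro", "aggregate_runs", "evaluate_scores",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class MetricsReport:
    ap: float
    f1: float
    auroc: float
    pro: float
    aupro: float = float("nan")
    threshold: float = float("nan")
    n_images: int = 0
    n_regions: int = 0


def _check_binary(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("need both classes present")
    return labels


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties half)."""
    return float(roc_auc_score(_check_binary(labels), np.asarray(scores, float)))


def average_precision(scores, labels) -> float:
    """Step integration of precision over recall."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() < 1:
        raise ValueError("need at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, float)))


def f1_at(scores, labels, threshold: float) -> float:
    """F1 of the classifier score >= threshold; 0/0 guarded to 0."""
    labels = _check_binary(labels)
    pred = np.asarray(scores, float) >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2.0 * p * r / (p + r)


def best_f1(scores, labels) -> tuple[float, float]:
    """Max F1 over all distinct thresholds; returns (f1, threshold)."""
    labels = _check_binary(labels)
    prec, rec, thr = precision_recall_curve(labels, np.asarray(scores, float))
    denom = prec + rec
    f1s = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1), 0.0)
    i = int(np.argmax(f1s[:-1])) if len(thr) else 0
    return float(f1s[i]), float(thr[min(i, len(thr) - 1)])


def _regions(masks: list) -> list:
    regs = []
    for mi, mask in enumerate(masks):
        lab, n = ndimage.label(np.asarray(mask) > 0, structure=_EIGHT)
        for r in range(1, n + 1):
            regs.append((mi, lab == r))
    return regs


def pro(score_maps: list, masks: list, threshold: float) -> float:
    """Per-region overlap at a fixed threshold (mean TP_n/(TP_n+FN_n))."""
    if len(score_maps) != len(masks):
        raise ValueError("need one mask per score map")
    regs = _regions(masks)
    if not regs:
        raise ValueError("no ground-truth regions in the mask set")
    preds = [np.asarray(s, float) >= threshold for s in score_maps]
    overlaps = [preds[mi][reg].mean() for mi, reg in regs]
    return float(np.mean(overlaps))


def aupro(score_maps: list, masks: list, fpr_limit: float = 0.3,
          n_thresholds: int = 200) -> float:
    """Area under the per-region-overlap vs FPR curve up to ``fpr_limit``,
    normalised to [0,1].  An extension of the fixed-threshold PRO for
    comparability with the anomaly-localisation literature."""
    if not 0.0 < fpr_limit <= 1.0:
        raise ValueError("fpr_limit must lie in (0, 1]")
    regs = _regions(masks)
    if not regs:
        raise ValueError("no ground-truth regions in the mask set")
    flat_scores = np.concatenate([np.asarray(s, float).ravel() for s in score_maps])
    flat_masks = np.concatenate([np.asarray(m).astype(bool).ravel() for m in masks])
    neg = flat_scores[~flat_masks]
    if neg.size == 0:
        raise ValueError("no normal pixels to define an FPR")
    qs = np.linspace(0.0, 1.0, n_thresholds)
    thresholds = np.unique(np.quantile(flat_scores, qs))
    fprs, pros = [], []
    for th in thresholds[::-1]:
        fpr = float((neg >= th).mean())
        preds = [np.asarray(s, float) >= th for s in score_maps]
        p = float(np.mean([preds[mi][reg].mean() for mi, reg in regs]))
        fprs.append(fpr)
        pros.append(p)
        if fpr >= 1.0:
            break
    fprs = np.asarray(fprs)
    pros = np.asarray(pros)
    # restrict to the [0, fpr_limit] segment, interpolating the right edge
    if fprs[-1] < fpr_limit:
        fprs = np.append(fprs, fpr_limit)
        pros = np.append(pros, pros[-1])
    keep = fprs <= fpr_limit
    edge = np.searchsorted(fprs, fpr_limit)
    if edge < len(fprs) and not keep[edge]:
        # interpolate PRO at exactly fpr_limit
        f0, f1_ = fprs[edge - 1], fprs[edge]
        p0, p1_ = pros[edge - 1], pros[edge]
        pe = p0 + (p1_ - p0) * (fpr_limit - f0) / max(f1_ - f0, 1e-12)
        fprs = np.append(fprs[keep], fpr_limit)
        pros = np.append(pros[keep], pe)
    else:
        fprs, pros = fprs[keep], pros[keep]
    if len(fprs) < 2:
        return 0.0
    return float(np.trapezoid(pros, fprs) / fpr_limit)


def aggregate_runs(reports: list) -> dict:
    """Sample mean and sd (n-1 denominator) per metric over repeated runs."""
    if not reports:
        raise ValueError("no reports to aggregate")
    out = {}
    for name in ("ap", "f1", "auroc", "pro", "aupro"):
        vals = np.asarray([getattr(r, name) for r in reports], float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[name] = (mean, sd)
    return out


def evaluate_scores(image_scores, image_labels, score_maps=None, masks=None,
                    pixel_threshold: float | None = None) -> MetricsReport:
    """Image-level AUROC/AP/F1 plus region-level PRO/AUPRO when maps given.

    The PRO operating threshold defaults to the pixel-level best-F1
    threshold on the evaluation set.
    """
    image_scores = np.asarray(image_scores, float)
    f1v, thr = best_f1(image_scores, image_labels)
    rep = MetricsReport(
        ap=average_precision(image_scores, image_labels),
        f1=f1v,
        auroc=auroc(image_scores, image_labels),
        pro=float("nan"),
        threshold=thr,
        n_images=len(image_scores),
    )
    if score_maps is not None and masks is not None:
        flat_s = np.concatenate([np.asarray(s, float).ravel() for s in score_maps])
        flat_m = np.concatenate([np.asarray(m).astype(int).ravel() for m in masks])
        if pixel_threshold is None:
            _, pixel_threshold = best_f1(flat_s, flat_m)
        rep.pro = pro(score_maps, masks, pixel_threshold)
        rep.aupro = aupro(score_maps, masks)
        rep.n_regions = len(_regions(masks))
        rep.threshold = float(pixel_threshold)
    return rep
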