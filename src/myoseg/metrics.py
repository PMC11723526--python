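"""Segmentation evaluation (IoU/Dice), k-fold cross-validation folds, and
the six classical auto-threshold baselines with a skeleton-quality
comparison.

IoU = TP / (TP + FP + FN) and Dice = 2TP / (2TP + FP + FN) are computed
from exact pixel confusion counts; the algebraic identity
Dice = 2*IoU / (1 + IoU) holds for every mask pair. Empty-vs-empty pairs
are scored 1.0 (logged), empty-vs-nonempty 0.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import filters as _filters

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "confusion",
    "iou",
    "dice",
    "mask_iou",
    "mask_dice",
    "THRESHOLD_METHODS",
    "threshold_segment",
    "make_folds",
    "crossval",
    "compare_methods",
]

THRESHOLD_METHODS = ("isodata", "li", "mean", "minimum", "otsu", "yen")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(pred, truth) -> ConfusionCounts:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shapes differ: pred {pred.shape} vs truth {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary {{0,1}}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        TP=int((p & t).sum()),
        FP=int((p & ~t).sum()),
        FN=int((~p & t).sum()),
        TN=int((~p & ~t).sum()),
    )


def iou(cc: ConfusionCounts) -> float:
    denom = cc.TP + cc.FP + cc.FN
    if denom == 0:
        logger.info("both masks empty: IoU defined as 1.0")
        return 1.0
    return cc.TP / denom


def dice(cc: ConfusionCounts) -> float:
    denom = 2 * cc.TP + cc.FP + cc.FN
    if denom == 0:
        logger.info("both masks empty: Dice defined as 1.0")
        return 1.0
    return 2 * cc.TP / denom


def mask_iou(pred, truth) -> float:
    return iou(confusion(pred, truth))


def mask_dice(pred, truth) -> float:
    return dice(confusion(pred, truth))


# ---------------------------------------------------------------------------
# auto-threshold baselines
# ---------------------------------------------------------------------------

_THRESH_FN = {
    "isodata": _filters.threshold_isodata,
    "li": _filters.threshold_li,
    "mean": _filters.threshold_mean,
    "minimum": _filters.threshold_minimum,
    "otsu": _filters.threshold_otsu,
    "yen": _filters.threshold_yen,
}


def threshold_segment(channel, method: str) -> np.ndarray:
    """Global histogram threshold by the named classical criterion;
    foreground = pixels strictly above the threshold."""
    if method not in _THRESH_FN:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_THRESH_FN)}")
    channel = np.asarray(channel)
    if channel.min() == channel.max():
        logger.warning("constant image: %s threshold undefined, empty mask returned", method)
        return np.zeros(channel.shape, np.uint8)
    try:
        t = _THRESH_FN[method](channel)
    except RuntimeError as e:  # e.g. 'minimum' on a histogram that never turns bimodal
        logger.warning("%s threshold failed (%s); empty mask returned", method, e)
        return np.zeros(channel.shape, np.uint8)
    return (channel > t).astype(np.uint8)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def make_folds(n_images: int, k: int = 5, seed: int = 0):
    """Image-level partition: list of (train_idx, test_idx), each image in
    test exactly once."""
    if k < 2:
        raise ValueError("k-fold cross-validation needs k >= 2")
    if n_images < k:
        raise ValueError(f"cannot split {n_images} images into {k} folds")
    from sklearn.model_selection import KFold

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n_images)))


def crossval(images, k: int = 5, seed: int = 0, run_fold=None) -> pd.DataFrame:
    """Run ``run_fold(train_items, test_items)`` on each image-level fold and
    aggregate the per-fold metric dicts (mean and std across folds).

    Returns a DataFrame with one row per fold plus aggregate rows.
    """
    images = list(images)
    folds = make_folds(len(images), k=k, seed=seed)
    rows = []
    for f, (tr, te) in enumerate(folds):
        metrics = run_fold([images[i] for i in tr], [images[i] for i in te]) if run_fold else {}
        rows.append({"fold": f, **metrics})
    df = pd.DataFrame(rows)
    if run_fold and len(df.columns) > 1:
        stats = df.drop(columns="fold").agg(["mean", "std"])
        stats.insert(0, "fold", stats.index)
        df = pd.concat([df, stats], ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# baseline comparison (learned/reference segmenter vs six thresholds)
# ---------------------------------------------------------------------------

def _branch_count(mask) -> int:
    from .postprocess import extract_branches, skeletonize

    return len(extract_branches(skeletonize(mask)).branches)


def compare_methods(scenes, methods=THRESHOLD_METHODS, segmenter=None, segmenter_name="Deep learning"):
    """Myotube-channel comparison table: IoU, Dice and skeleton branch count
    per method, columns ordered segmenter-first like a results table.

    ``scenes`` yields (image, ground_truth) pairs; ``segmenter`` maps an
    image to a binary myotube mask (defaults to ground truth passthrough).
    """
    per_method: dict[str, dict] = {}
    names = [segmenter_name, *methods]
    acc = {m: {"iou": [], "dice": [], "branches": [], "branches_true": []} for m in names}
    for image, gt in scenes:
        px = image.pixels if hasattr(image, "pixels") else np.asarray(image)
        truth = gt.myotube_mask
        masks = {segmenter_name: (segmenter(image) if segmenter else truth)}
        for m in methods:
            masks[m] = threshold_segment(px[0], m)
        for name, mask in masks.items():
            cc = confusion((np.asarray(mask) > 0).astype(np.uint8), truth)
            acc[name]["iou"].append(iou(cc))
            acc[name]["dice"].append(dice(cc))
            acc[name]["branches"].append(_branch_count(mask))
            acc[name]["branches_true"].append(_branch_count(truth))
    for name, d in acc.items():
        per_method[name] = {
            "IoU": float(np.mean(d["iou"])),
            "Dice": float(np.mean(d["dice"])),
            "mean_branches": float(np.mean(d["branches"])),
            "mean_branches_truth": float(np.mean(d["branches_true"])),
        }
    return pd.DataFrame(per_method)[list(names)]
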