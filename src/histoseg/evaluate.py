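"""Pixel-based confusion-matrix evaluation of tumour segmentation.

Scoring is per pixel, not per object: a detection that covers only part of a
tumour region is penalized for every missed pixel.  The positive class is
tumour; everything else (after merging the stroma and lymphoid/necrosis
subtypes) is negative.  Regions a pathologist could not call — e.g. poorly
differentiated areas on IHC — are carried as an exclusion mask and removed
from scoring, as are ground-truth background pixels by default (the task is
cancerous-cell segmentation, not tissue detection; set
``include_background=True`` to score background as non-tumour instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mrf import MERGED_CLASSES

_TUMOUR = MERGED_CLASSES.index("tumour")
_BACKGROUND = MERGED_CLASSES.index("background")

#: Overlay colours: green = TP, red = TN, yellow = FN, blue = FP.
OVERLAY_COLOURS = {
    "tp": (0, 170, 0),
    "tn": (200, 0, 0),
    "fn": (230, 220, 0),
    "fp": (0, 70, 230),
    "excluded": (60, 60, 60),
}


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts of the tumour / non-tumour confusion matrix."""

    tp: int
    fp: int
    tn: int
    fn: int
    excluded: int = 0

    @property
    def evaluable(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def total(self) -> int:
        return self.evaluable + self.excluded


@dataclass(frozen=True)
class EvalMetrics:
    """Derived rates; entries whose denominator was zero are NaN and listed
    in ``undefined``."""

    accuracy: float
    tp_rate: float
    fp_rate: float
    fn_rate: float
    tn_rate: float
    precision: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "tp_rate": self.tp_rate,
            "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate,
            "tn_rate": self.tn_rate,
            "precision": self.precision,
        }


def confusion(
    pred: np.ndarray,
    truth: np.ndarray,
    exclude: np.ndarray | None = None,
    include_background: bool = False,
) -> ConfusionCounts:
    """Pixelwise tumour-vs-rest confusion counts over non-excluded sites.

    ``pred`` and ``truth`` are merged three-class labellings (tumour=0,
    non_tumour=1, background=2) on the same raster.  ``exclude`` marks
    don't-care pixels.  By default ground-truth background is also excluded;
    with ``include_background=True`` it is scored as non-tumour.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"prediction {pred.shape} and truth {truth.shape} rasters differ")
    valid = np.ones(pred.shape, dtype=bool)
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        if exclude.shape != pred.shape:
            raise ValueError(f"exclusion mask shape {exclude.shape} differs")
        valid &= ~exclude
    if not include_background:
        valid &= truth != _BACKGROUND
    truth_pos = truth == _TUMOUR
    pred_pos = pred == _TUMOUR
    tp = int(np.sum(valid & truth_pos & pred_pos))
    fn = int(np.sum(valid & truth_pos & ~pred_pos))
    fp = int(np.sum(valid & ~truth_pos & pred_pos))
    tn = int(np.sum(valid & ~truth_pos & ~pred_pos))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, excluded=int(pred.size - valid.sum()))


def metrics(counts: ConfusionCounts, footnote_fp_rate: bool = False) -> EvalMetrics:
    """Accuracy, rates and precision from confusion counts.

    The false-positive rate is FP/(FP+TN), the complement of the
    true-negative rate.  ``footnote_fp_rate=True`` switches to the variant
    FP/(FP+TP).  Zero denominators give NaN entries flagged in
    ``undefined`` rather than raising.
    """
    undefined: set[str] = set()

    def safe(name: str, num: int, den: int) -> float:
        if den == 0:
            undefined.add(name)
            return float("nan")
        return num / den

    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    fp_den = (fp + tp) if footnote_fp_rate else (fp + tn)
    return EvalMetrics(
        accuracy=safe("accuracy", tp + tn, tp + tn + fp + fn),
        tp_rate=safe("tp_rate", tp, tp + fn),
        fp_rate=safe("fp_rate", fp, fp_den),
        fn_rate=safe("fn_rate", fn, fn + tp),
        tn_rate=safe("tn_rate", tn, tn + fp),
        precision=safe("precision", tp, tp + fp),
        undefined=frozenset(undefined),
    )


def overlay(
    pred: np.ndarray,
    truth: np.ndarray,
    exclude: np.ndarray | None = None,
    include_background: bool = False,
) -> np.ndarray:
    """RGB visualization of the pixel outcome classes.

    Green = true positive, red = true negative, yellow = false negative,
    blue = false positive; excluded pixels dark grey.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth rasters differ")
    valid = np.ones(pred.shape, dtype=bool)
    if exclude is not None:
        valid &= ~np.asarray(exclude, dtype=bool)
    if not include_background:
        valid &= truth != _BACKGROUND
    img = np.empty((*pred.shape, 3), dtype=np.uint8)
    img[...] = OVERLAY_COLOURS["excluded"]
    truth_pos = truth == _TUMOUR
    pred_pos = pred == _TUMOUR
    img[valid & truth_pos & pred_pos] = OVERLAY_COLOURS["tp"]
    img[valid & ~truth_pos & ~pred_pos] = OVERLAY_COLOURS["tn"]
    img[valid & truth_pos & ~pred_pos] = OVERLAY_COLOURS["fn"]
    img[valid & ~truth_pos & pred_pos] = OVERLAY_COLOURS["fp"]
    return img
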