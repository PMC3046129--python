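"""End-to-end convenience wrapper: train -> segment -> merge -> evaluate."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import ConfusionCounts, EvalMetrics, confusion, metrics
from .mrf import EnergyTrace, MRFConfig, merge_non_tumour, relax
from .texture import ClassModel, blue_channel, learn_class_params


@dataclass(frozen=True)
class SegmentationResult:
    """Outputs of one supervised segmentation run."""

    labels4: np.ndarray
    labels3: np.ndarray
    model: ClassModel
    trace: EnergyTrace
    counts: ConfusionCounts | None = None
    metrics: EvalMetrics | None = None


def run_pipeline(
    image: np.ndarray,
    training_mask: np.ndarray,
    config: MRFConfig | None = None,
    truth4: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
    include_background: bool = False,
) -> SegmentationResult:
    """Segment an RGB tissue-core image given training regions.

    Learns the four-class Gaussian blue-channel model from ``training_mask``
    (0 = unlabelled, 1..4 = classes), runs the configured MRF relaxation,
    merges the two non-tumour subtypes, and — when a four-class ground truth
    is supplied — scores tumour vs non-tumour per pixel.
    """
    config = config or MRFConfig()
    features = blue_channel(image)
    model = learn_class_params(features, training_mask)
    labels4, trace = relax(features, model, config)
    labels3 = merge_non_tumour(labels4)
    counts = result_metrics = None
    if truth4 is not None:
        counts = confusion(
            labels3,
            merge_non_tumour(truth4),
            exclude=exclude,
            include_background=include_background,
        )
        result_metrics = metrics(counts)
    return SegmentationResult(
        labels4=labels4,
        labels3=labels3,
        model=model,
        trace=trace,
        counts=counts,
        metrics=result_metrics,
    )
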