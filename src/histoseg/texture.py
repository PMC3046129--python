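"""Blue-channel texture features and supervised class statistics.

In both H&E and haematoxylin-counterstained IHC material, nuclei stain blue,
and the blue channel carries more discriminative information for separating
tumour from other tissue than grey-scale or the red/green channels.  The
feature image is therefore simply the blue component per site, and each
tissue class is summarized by the mean and variance of that feature over a
user-drawn training region — the Gaussian parameters that feed the MRF
likelihood term.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Canonical class order of the default four-class pipeline.
DEFAULT_CLASSES = ("tumour", "stroma", "lymphoid_necrosis", "background")

#: Variance floor (intensity^2) keeping the Gaussian energy finite on
#: degenerate constant training regions.
VARIANCE_FLOOR = 1.0


@dataclass(frozen=True)
class ClassModel:
    """Per-class Gaussian parameters of the blue-channel feature."""

    class_names: tuple[str, ...]
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        variances = np.asarray(self.variances, dtype=float)
        if means.shape != variances.shape or means.ndim != 1:
            raise ValueError("means and variances must be 1-D arrays of equal length")
        if len(self.class_names) != means.size:
            raise ValueError("class_names length must match the number of classes")
        if means.size < 2:
            raise ValueError("need at least two classes")
        if np.any(variances <= 0):
            raise ValueError("variances must be strictly positive")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "variances", variances)

    @property
    def n_classes(self) -> int:
        return self.means.size

    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_names": list(self.class_names),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            class_names=tuple(payload["class_names"]),
            means=np.asarray(payload["means"], dtype=float),
            variances=np.asarray(payload["variances"], dtype=float),
        )


def blue_channel(img: np.ndarray) -> np.ndarray:
    """Extract the blue component per site as the feature image."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(
            "expected an H x W x 3 RGB image; grayscale input has no blue "
            "channel — supply an RGB image"
        )
    return img[..., 2].astype(float)


def learn_class_params(
    features: np.ndarray,
    training_mask: np.ndarray,
    class_names: tuple[str, ...] = DEFAULT_CLASSES,
    variance_floor: float = VARIANCE_FLOOR,
) -> ClassModel:
    """Estimate per-class mean and variance from labelled training regions.

    ``training_mask`` uses 0 for unlabelled pixels and ``i + 1`` for class
    ``class_names[i]`` (regions are disjoint by construction).  The variance
    is the population variance (divide by n) floored at ``variance_floor``.

    Raises ``ValueError`` if any class has no training pixels; a single-pixel
    region triggers the floor with a warning.
    """
    features = np.asarray(features, dtype=float)
    training_mask = np.asarray(training_mask)
    if features.shape != training_mask.shape:
        raise ValueError(
            f"feature {features.shape} and mask {training_mask.shape} rasters differ"
        )
    means = np.empty(len(class_names))
    variances = np.empty(len(class_names))
    for i, name in enumerate(class_names):
        sel = features[training_mask == i + 1]
        if sel.size == 0:
            raise ValueError(f"training region for class {name!r} is empty")
        if sel.size == 1:
            warnings.warn(
                f"class {name!r} has a single training pixel; variance floored",
                stacklevel=2,
            )
        means[i] = sel.mean()
        variances[i] = max(sel.var(), variance_floor)
    return ClassModel(class_names=tuple(class_names), means=means, variances=variances)
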