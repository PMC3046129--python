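"""Synthetic tissue-core images with planted ground truth.

No imaging data ships with the package, so this module is the test surface:
it plants a blobby four-class geometry (tumour, stroma, lymphoid/necrosis,
background), draws the blue-channel feature i.i.d. from the class-conditional
Gaussians the segmentation model assumes, and can compose a full RGB image
through the Lambert–Beer forward model with class-specific stain amounts.
Because the generator's statistical structure matches the segmentation
model's assumptions exactly, end-to-end accuracy against the planted truth
is a meaningful recovery metric — it measures the optimizer and the
estimator, not model mismatch.

Two standard difficulty regimes: the "easy" suite uses well-separated class
means (40/100/160/220, sigma 15); the "hard" suite raises sigma to 35 so
class likelihoods overlap and the spatial prior has to do real work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .stains import StainMatrix, compose_rgb, stain_preset
from .texture import DEFAULT_CLASSES

#: Easy-suite class means and spread for the blue-channel feature.
DEFAULT_MEANS = (40.0, 100.0, 160.0, 220.0)
DEFAULT_SIGMA = 15.0
#: Hard-suite spread: adjacent class likelihoods overlap substantially.
HARD_SIGMA = 35.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic tissue-core sample.

    ``class_fractions`` are target area fractions (must sum to 1) in the
    canonical class order (tumour, stroma, lymphoid/necrosis, background).
    ``blob_sigma`` controls the spatial scale of the planted regions.
    ``render_mode`` is ``"gaussian"`` (RGB = replicated feature channel, blue
    channel IS the Gaussian feature) or ``"stain"`` (full Lambert–Beer
    composition from ``stain_amounts`` per class).
    """

    shape: tuple[int, int] = (256, 256)
    class_fractions: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)
    class_means: tuple[float, ...] = DEFAULT_MEANS
    class_sigmas: tuple[float, ...] = (DEFAULT_SIGMA,) * 4
    blob_sigma: float = 12.0
    train_erosion: int = 4
    exclusion_fraction: float = 0.0
    render_mode: str = "gaussian"
    # per-class (haematoxylin, eosin) amounts for render_mode="stain"
    stain_amounts: tuple[tuple[float, float], ...] = (
        (0.85, 0.30),
        (0.25, 0.60),
        (0.60, 0.20),
        (0.03, 0.03),
    )
    stain_system: str = "h&e"

    def __post_init__(self):
        if len(self.class_fractions) != len(self.class_means) or len(
            self.class_means
        ) != len(self.class_sigmas):
            raise ValueError("per-class parameter tuples must have equal length")
        if self.render_mode not in ("gaussian", "stain"):
            raise ValueError("render_mode must be 'gaussian' or 'stain'")
        if not 0 <= self.exclusion_fraction < 1:
            raise ValueError("exclusion_fraction must lie in [0, 1)")

    def hard(self) -> "SyntheticSpec":
        """The overlapping-texture variant of this spec."""
        return replace(self, class_sigmas=(HARD_SIGMA,) * len(self.class_sigmas))


@dataclass(frozen=True)
class SyntheticSample:
    """A rendered sample: image, feature, truth and masks, all one raster."""

    rgb: np.ndarray
    feature: np.ndarray
    truth: np.ndarray
    training_mask: np.ndarray
    exclusion_mask: np.ndarray
    spec: SyntheticSpec
    seed: int


def make_layout(spec: SyntheticSpec, seed: int | np.random.Generator) -> np.ndarray:
    """Blobby class partition with target area fractions.

    White noise is smoothed to ``blob_sigma`` and cut at the quantiles of
    the cumulative class fractions, so realized fractions match the targets
    to within the granularity of the raster.  Deterministic per seed.
    """
    fractions = np.asarray(spec.class_fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-8:
        raise ValueError(f"class fractions must sum to 1, got {fractions.sum()}")
    if np.any(fractions < 0):
        raise ValueError("class fractions must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    field_ = ndimage.gaussian_filter(rng.standard_normal(spec.shape), spec.blob_sigma)
    cum = np.cumsum(fractions)[:-1]
    thresholds = np.quantile(field_, cum)
    return np.sum(field_[..., None] > thresholds[None, None, :], axis=-1).astype(np.int64)


def _blob_mask(shape, fraction, blob_sigma, rng) -> np.ndarray:
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), blob_sigma)
    return field_ > np.quantile(field_, 1.0 - fraction)


def render(
    truth: np.ndarray,
    spec: SyntheticSpec,
    seed: int | np.random.Generator,
    stain_matrix: StainMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render (rgb, feature, training_mask, exclusion_mask) for a layout.

    The feature (blue channel) is drawn i.i.d. N(mu_class, sigma_class^2)
    per pixel, rounded and clipped to [0, 255].  Training masks are eroded
    class cores (guaranteed pure, away from boundaries); a class whose core
    erodes away falls back to its full region.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = np.asarray(truth)
    means = np.asarray(spec.class_means)[truth]
    sigmas = np.asarray(spec.class_sigmas)[truth]
    feature = np.clip(np.rint(rng.normal(means, sigmas)), 0, 255)

    if spec.render_mode == "stain":
        matrix = stain_matrix or stain_preset(spec.stain_system)
        amounts = np.asarray(spec.stain_amounts, dtype=float)[truth]
        rgb = compose_rgb(amounts, matrix)
    else:
        rgb = np.repeat(feature[..., None], 3, axis=2).astype(np.uint8)

    training_mask = np.zeros(truth.shape, dtype=np.uint8)
    structure = ndimage.generate_binary_structure(2, 2)
    for c in range(len(spec.class_fractions)):
        region = truth == c
        if not region.any():
            continue
        core = ndimage.binary_erosion(region, structure, iterations=spec.train_erosion)
        training_mask[core if core.any() else region] = c + 1

    exclusion = _blob_mask(truth.shape, spec.exclusion_fraction, spec.blob_sigma, rng)
    return rgb, feature, training_mask, exclusion


def generate(spec: SyntheticSpec, seed: int) -> SyntheticSample:
    """Layout + render in one reproducible call."""
    ss = np.random.SeedSequence(seed)
    layout_rng, render_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    truth = make_layout(spec, layout_rng)
    rgb, feature, training_mask, exclusion = render(truth, spec, render_rng)
    return SyntheticSample(
        rgb=rgb,
        feature=feature,
        truth=truth,
        training_mask=training_mask,
        exclusion_mask=exclusion,
        spec=spec,
        seed=seed,
    )


def planted_disks(
    shape: tuple[int, int] = (256, 256),
    n_disks: int = 12,
    radius_range: tuple[int, int] = (14, 22),
    disk_amount: float = 1.2,
    field_amount: float = 0.1,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Haematoxylin amount map with planted nucleus-like disks.

    Dark disks (high amount) on a light field plus Gaussian noise, clipped
    at zero — the standard fixture for the nuclear-extraction pipeline.
    Returns (amount map, boolean truth mask).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    truth = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_disks):
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        cy = int(rng.integers(r, h - r))
        cx = int(rng.integers(r, w - r))
        truth |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    amount = np.where(truth, disk_amount, field_amount)
    amount = np.maximum(amount + rng.normal(0.0, noise_sigma, shape), 0.0)
    return amount, truth
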