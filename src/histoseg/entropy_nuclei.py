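"""Multistage maximum-entropy segmentation of nuclear architecture.

Nuclei take up haematoxylin strongly, so they sit at the high end of the
haematoxylin optical-density distribution.  The extraction pipeline is
histogram-driven and fully unsupervised:

1. quantize the haematoxylin amount map to 8 bits,
2. split the intensity histogram into four equal-width sub-ranges and place a
   maximum-entropy (Kapur) cut inside each, giving eight intensity layers,
3. histogram the eight layer indices and place one more maximum-entropy cut
   to separate "nuclei" (high layers) from "non-nuclei",
4. clean the binary mask with a neighbourhood mode (majority) filter.

The Kapur criterion picks the threshold t maximizing the sum of the Shannon
entropies of the two renormalized class histograms below and above t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Default mode-filter neighbourhood radius (window (2r+1) x (2r+1)).
DEFAULT_MODE_RADIUS = 3

#: Equal-width sub-ranges of the 8-bit histogram for the eight-layer stage.
SUBRANGES = ((0, 63), (64, 127), (128, 191), (192, 255))


class DegenerateInputWarning(UserWarning):
    """Raised when a histogram stage falls back to a degenerate default."""


@dataclass(frozen=True)
class ThresholdSet:
    """Cut points from the eight-layer stage, one per equal-width sub-range."""

    cuts: tuple[int, ...]
    subranges: tuple[tuple[int, int], ...] = SUBRANGES
    degenerate: tuple[bool, ...] = (False, False, False, False)

    def layer_bounds(self) -> tuple[int, ...]:
        """Upper (inclusive) intensity bound of each of the 8 layers."""
        bounds = []
        for (lo, hi), t in zip(self.subranges, self.cuts):
            bounds.extend([t, hi])
        return tuple(bounds)


@dataclass(frozen=True)
class NucleiResult:
    """Binary nuclei mask plus the intermediate products of the pipeline."""

    mask: np.ndarray
    layers: np.ndarray
    thresholds: ThresholdSet
    binary_raw: np.ndarray
    layer_cut: int
    quantization: tuple[float, float]


def histogram(img: np.ndarray, levels: int = 256) -> np.ndarray:
    """Normalized intensity histogram of a quantized single-channel image."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("cannot histogram an empty image")
    flat = img.ravel().astype(np.int64)
    if flat.min() < 0 or flat.max() >= levels:
        raise ValueError(f"image values must lie in [0, {levels - 1}]")
    counts = np.bincount(flat, minlength=levels).astype(float)
    return counts / counts.sum()


def entropy(hist: np.ndarray, lo: int = 0, hi: int | None = None) -> float:
    """Shannon entropy (bits) of the histogram restricted to [lo, hi], renormalized.

    The convention 0*log(0) = 0 applies; a zero-mass sub-range is defined as
    entropy 0 and flagged with :class:`DegenerateInputWarning`.
    """
    hist = np.asarray(hist, dtype=float)
    if hi is None:
        hi = hist.size - 1
    if lo > hi:
        raise ValueError(f"lo must not exceed hi, got [{lo}, {hi}]")
    sub = hist[lo : hi + 1]
    mass = sub.sum()
    if mass == 0:
        warnings.warn(
            f"zero probability mass in [{lo}, {hi}]; entropy defined as 0",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return 0.0
    p = sub[sub > 0] / mass
    return float(-(p * np.log2(p)).sum())


def max_entropy_cut(hist: np.ndarray, lo: int, hi: int) -> int:
    """Maximum-entropy (Kapur) cut point within [lo, hi].

    Returns the t in [lo, hi-1] maximizing E(P|[lo,t]) + E(P|[t+1,hi]) over
    the renormalized halves; ties break to the smallest t.  If all mass sits
    at a single level, that level is returned with a degenerate-input warning.
    """
    hist = np.asarray(hist, dtype=float)
    if hi - lo < 1:
        raise ValueError(f"need at least two levels, got [{lo}, {hi}]")
    sub = hist[lo : hi + 1]
    total = sub.sum()
    if total == 0:
        raise ValueError(f"no probability mass in [{lo}, {hi}]")
    nz = np.nonzero(sub)[0]
    if nz.size == 1:
        level = lo + int(nz[0])
        warnings.warn(
            f"all mass at level {level}; cut is degenerate",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return level

    p = sub / total
    # Entropy of a renormalized prefix of weight w: log2(w) - S/w where
    # S = sum p*log2(p) over the prefix; analogously for the suffix.
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    w1 = np.cumsum(p)[:-1]  # weight of [lo, t], t = lo..hi-1
    s1 = np.cumsum(plogp)[:-1]
    w2 = 1.0 - w1
    s2 = plogp.sum() - s1

    def _half(w, s):
        # Kapur half-criterion log2(w) - S/w; an empty class drives it to
        # -inf, so cuts stranding all mass on one side are never chosen.
        out = np.full_like(w, -np.inf)
        pos = w > 0
        out[pos] = np.log2(w[pos]) - s[pos] / w[pos]
        return out

    criterion = _half(w1, s1) + _half(w2, s2)
    return lo + int(np.argmax(criterion))


def eight_layer_decompose(img: np.ndarray) -> tuple[np.ndarray, ThresholdSet]:
    """Split an 8-bit image into eight intensity layers.

    The histogram is divided into four equal-width sub-ranges ([0,63],
    [64,127], [128,191], [192,255]); a maximum-entropy cut inside each, plus
    the three sub-range boundaries, partitions [0, 255] into eight contiguous
    intervals.  Each pixel gets its interval index 0..7, ascending with
    intensity.  A sub-range without mass takes its midpoint as the cut and is
    flagged.
    """
    img = np.asarray(img)
    hist = histogram(img, levels=256)
    cuts, degenerate = [], []
    for lo, hi in SUBRANGES:
        if hist[lo : hi + 1].sum() == 0:
            cuts.append((lo + hi) // 2)
            degenerate.append(True)
            warnings.warn(
                f"sub-range [{lo}, {hi}] has no mass; cut defaults to midpoint",
                DegenerateInputWarning,
                stacklevel=2,
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateInputWarning)
            single = np.nonzero(hist[lo : hi + 1])[0].size == 1
            cuts.append(max_entropy_cut(hist, lo, hi))
        if single:
            degenerate.append(True)
            warnings.warn(
                f"sub-range [{lo}, {hi}] has a single populated level; cut degenerate",
                DegenerateInputWarning,
                stacklevel=2,
            )
        else:
            degenerate.append(False)
    thresholds = ThresholdSet(
        cuts=tuple(cuts), degenerate=tuple(degenerate)
    )
    bounds = np.asarray(thresholds.layer_bounds())
    layers = np.searchsorted(bounds, img.astype(np.int64), side="left").astype(np.uint8)
    return layers, thresholds


def binarize_nuclei(layers: np.ndarray) -> tuple[np.ndarray, int]:
    """Two-class maximum-entropy cut on the eight layer indices.

    Pixels whose layer index lies above the cut (high haematoxylin OD) are
    nuclei.  Returns the boolean mask and the cut used.  A single-layer input
    yields an all-False mask, flagged.
    """
    layers = np.asarray(layers)
    if layers.max(initial=0) > 7:
        raise ValueError("expected an 8-layer image with values in 0..7")
    hist = histogram(layers, levels=8)
    if np.nonzero(hist)[0].size == 1:
        warnings.warn(
            "single populated layer; no nuclei extracted",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return np.zeros(layers.shape, dtype=bool), 7
    cut = max_entropy_cut(hist, 0, 7)
    return layers > cut, cut


def mode_filter(img: np.ndarray, radius: int = DEFAULT_MODE_RADIUS) -> np.ndarray:
    """Neighbourhood mode (majority) filter for discrete-valued images.

    Each output pixel is the most frequent value in the (2r+1) x (2r+1)
    window centred on it; windows are clipped at image borders and ties break
    to the smallest value.  Used to remove spurious false positives and
    recover low-contrast interior pixels after thresholding.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("mode_filter expects a 2-D image")
    values = np.unique(img)
    h, w = img.shape
    best_count = np.zeros((h, w), dtype=np.int64)
    best_value = np.empty((h, w), dtype=img.dtype)
    for v in values:  # ascending: strict > keeps the smallest tied value
        count = _box_count(img == v, radius)
        better = count > best_count
        best_count[better] = count[better]
        best_value[better] = v
    return best_value


def _box_count(mask: np.ndarray, r: int) -> np.ndarray:
    """Count of True cells in the border-clipped (2r+1)^2 window of each pixel."""
    h, w = mask.shape
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=sat[1:, 1:])
    rows = np.arange(h)
    cols = np.arange(w)
    top = np.maximum(rows - r, 0)
    bot = np.minimum(rows + r, h - 1) + 1
    left = np.maximum(cols - r, 0)
    right = np.minimum(cols + r, w - 1) + 1
    return (
        sat[np.ix_(bot, right)]
        - sat[np.ix_(top, right)]
        - sat[np.ix_(bot, left)]
        + sat[np.ix_(top, left)]
    )


def quantize_to_8bit(img: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Linear min–max quantization of a real-valued map to uint8.

    Returns the quantized image and the (min, max) used, so the scaling is
    reproducible.  A constant image maps to all zeros with a flag.
    """
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        warnings.warn(
            "constant image; quantization maps everything to 0",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return np.zeros(img.shape, dtype=np.uint8), (lo, hi)
    q = np.rint(255.0 * (img - lo) / (hi - lo)).astype(np.uint8)
    return q, (lo, hi)


def extract_nuclei(
    haematoxylin_amount: np.ndarray, radius: int = DEFAULT_MODE_RADIUS
) -> NucleiResult:
    """Full nuclear-architecture extraction from a haematoxylin amount map.

    Pipeline: min–max 8-bit quantization -> eight-layer maximum-entropy
    decomposition -> two-class layer cut -> mode filter.  Because the stages
    act on ranks of intensity only, the mask is invariant to any monotone
    rescaling of the input.  Callers supplying raw transmitted intensity
    (bright nuclei = low values) must negate it first: the high side of the
    cut is taken as nuclei.
    """
    amount = np.asarray(haematoxylin_amount, dtype=float)
    if amount.ndim != 2:
        raise ValueError("expected a single-channel haematoxylin amount map")
    quant, scale = quantize_to_8bit(amount)
    if scale[0] == scale[1]:
        empty = np.zeros(amount.shape, dtype=bool)
        return NucleiResult(
            mask=empty,
            layers=np.zeros(amount.shape, dtype=np.uint8),
            thresholds=ThresholdSet(cuts=(31, 95, 159, 223), degenerate=(True,) * 4),
            binary_raw=empty,
            layer_cut=7,
            quantization=scale,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateInputWarning)
        layers, thresholds = eight_layer_decompose(quant)
        binary, cut = binarize_nuclei(layers)
    mask = mode_filter(binary.astype(np.uint8), radius=radius).astype(bool)
    return NucleiResult(
        mask=mask,
        layers=layers,
        thresholds=thresholds,
        binary_raw=binary,
        layer_cut=cut,
        quantization=scale,
    )
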