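import numpy as np
import pytest

from histoseg.texture import ClassModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def four_class_model():
    """The easy-suite class model: well-separated blue-channel Gaussians."""
    return ClassModel(
        class_names=("tumour", "stroma", "lymphoid_necrosis", "background"),
        means=np.array([40.0, 100.0, 160.0, 220.0]),
        variances=np.array([15.0**2] * 4),
    )


@pytest.fixture
def two_class_model():
    return ClassModel(
        class_names=("a", "b"),
        means=np.array([60.0, 180.0]),
        variances=np.array([15.0**2, 15.0**2]),
    )


def kapur_brute(hist, lo, hi):
    """Exhaustive maximum-entropy cut: scan every partition of the populated
    bins, compare criteria, return the smallest t of the winning plateau.

    Cuts within a run of empty bins produce mathematically identical
    partitions, so candidates are enumerated per populated split; the
    smallest t realizing the best partition is the last populated bin on its
    left side.
    """
    hist = np.asarray(hist, dtype=float)
    populated = [i for i in range(lo, hi + 1) if hist[i] > 0]
    assert len(populated) >= 2

    def shannon(sub):
        p = sub[sub > 0] / sub.sum()
        return float(-(p * np.log2(p)).sum())

    best_t, best_v = None, -np.inf
    for split in range(1, len(populated)):
        t = populated[split - 1]  # smallest t with this left/right partition
        if t > hi - 1:
            continue
        v = shannon(hist[lo : t + 1]) + shannon(hist[t + 1 : hi + 1])
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def mode_brute(img, r):
    """Per-pixel window counting: most frequent value, clipped windows,
    ties to the smallest value."""
    h, w = img.shape
    out = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            window = img[max(0, i - r) : i + r + 1, max(0, j - r) : j + r + 1]
            values, counts = np.unique(window, return_counts=True)
            out[i, j] = values[np.argmax(counts)]  # first max = smallest value
    return out
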