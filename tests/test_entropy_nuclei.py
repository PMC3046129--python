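import numpy as np
import pytest

from conftest import kapur_brute, mode_brute
from histoseg.entropy_nuclei import (
    DegenerateInputWarning,
    binarize_nuclei,
    eight_layer_decompose,
    entropy,
    extract_nuclei,
    histogram,
    max_entropy_cut,
    mode_filter,
    quantize_to_8bit,
)
from histoseg.simulate import planted_disks


class TestHistogram:
    def test_constant_image_is_delta(self):
        h = histogram(np.full((4, 4), 5), levels=256)
        assert h[5] == 1.0 and h.sum() == 1.0

    def test_two_value_split(self):
        img = np.array([[0, 0], [9, 9]])
        h = histogram(img, levels=10)
        np.testing.assert_array_equal(h[[0, 9]], [0.5, 0.5])

    def test_normalization_exact(self, rng):
        img = rng.integers(0, 256, 1000)
        assert histogram(img).sum() == 1.0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            histogram(np.empty((0,), dtype=int))


class TestEntropy:
    @pytest.mark.parametrize(
        "hist, expected",
        [
            (np.eye(256)[7], 0.0),  # delta
            (np.full(256, 1 / 256), 8.0),  # uniform over 256 levels
            (np.array([0.25, 0.25, 0.25, 0.25]), 2.0),  # uniform over 4
        ],
    )
    def test_known_entropies(self, hist, expected):
        assert entropy(hist) == pytest.approx(expected, abs=1e-12)

    def test_zero_mass_flagged_as_zero(self):
        h = np.zeros(16)
        h[10] = 1.0
        with pytest.warns(DegenerateInputWarning):
            assert entropy(h, 0, 5) == 0.0


class TestMaxEntropyCut:
    def test_two_spike_tie_breaks_to_smallest(self):
        h = np.zeros(256)
        h[10], h[200] = 0.4, 0.6
        assert max_entropy_cut(h, 0, 255) == 10

    def test_mirror_relation_under_reflection(self, rng):
        # Cutting the reversed histogram at t' induces the same partition of
        # populated bins as cutting the original at 254 - t'; with smallest-t
        # tie-breaking, t' maps to the *upper* end of the winning plateau.
        h = np.zeros(256)
        idx = rng.choice(256, 20, replace=False)
        h[idx] = rng.random(20)
        h /= h.sum()
        t = max_entropy_cut(h, 0, 255)
        t_rev = max_entropy_cut(h[::-1].copy(), 0, 255)
        populated = np.nonzero(h)[0]
        plateau_end = populated[populated > t].min() - 1
        assert 254 - t_rev == plateau_end

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            h = np.zeros(256)
            idx = rng.choice(256, rng.integers(2, 50), replace=False)
            h[idx] = rng.random(idx.size)
            h /= h.sum()
            assert max_entropy_cut(h, 0, 255) == kapur_brute(h, 0, 255)

    def test_degenerate_single_level(self):
        h = np.zeros(256)
        h[42] = 1.0
        with pytest.warns(DegenerateInputWarning):
            assert max_entropy_cut(h, 0, 255) == 42


class TestEightLayerDecompose:
    def test_constant_image_flags_degenerate_subranges(self):
        with pytest.warns(DegenerateInputWarning):
            layers, thr = eight_layer_decompose(np.full((8, 8), 100, dtype=np.uint8))
        assert np.unique(layers).size == 1
        assert sum(thr.degenerate) >= 3

    def test_eight_distinct_levels_match_per_subrange_oracle(self, rng):
        levels = np.array([10, 40, 70, 100, 130, 160, 200, 230])
        img = rng.choice(levels, size=(64, 64), p=np.linspace(1, 2, 8) / np.linspace(1, 2, 8).sum())
        layers, thr = eight_layer_decompose(img.astype(np.uint8))
        assert np.unique(layers).size == 8
        hist = histogram(img, 256)
        expected = tuple(
            kapur_brute(hist, lo, hi) for lo, hi in ((0, 63), (64, 127), (128, 191), (192, 255))
        )
        assert thr.cuts == expected

    def test_layer_index_monotone_in_intensity(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        layers, _ = eight_layer_decompose(img)
        order = np.argsort(img.ravel(), kind="stable")
        assert np.all(np.diff(layers.ravel()[order]) >= 0)


class TestBinarizeNuclei:
    def test_all_zero_layers_empty_mask(self):
        with pytest.warns(DegenerateInputWarning):
            mask, _ = binarize_nuclei(np.zeros((4, 4), dtype=np.uint8))
        assert not mask.any()

    def test_two_layer_split(self):
        layers = np.array([[1, 1, 6, 6]] * 4, dtype=np.uint8)
        mask, cut = binarize_nuclei(layers)
        assert 1 <= cut < 6
        np.testing.assert_array_equal(mask, layers == 6)

    def test_partition_conserves_pixels(self, rng):
        layers = rng.integers(0, 8, (16, 16)).astype(np.uint8)
        mask, _ = binarize_nuclei(layers)
        assert mask.sum() + (~mask).sum() == layers.size


class TestModeFilter:
    def test_constant_image_idempotent(self):
        img = np.full((10, 10), 3, dtype=np.uint8)
        np.testing.assert_array_equal(mode_filter(img), img)

    def test_isolated_pixel_removed(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[4, 4] = 1
        assert mode_filter(img, radius=3)[4, 4] == 0

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_matches_window_counting_oracle(self, rng, radius):
        img = rng.integers(0, 4, (20, 20)).astype(np.uint8)
        np.testing.assert_array_equal(mode_filter(img, radius), mode_brute(img, radius))

    def test_never_introduces_absent_values(self, rng):
        img = rng.choice([2, 5, 9], size=(15, 15)).astype(np.uint8)
        assert set(np.unique(mode_filter(img))) <= {2, 5, 9}

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            mode_filter(np.zeros((3, 3), dtype=np.uint8), radius=0)


class TestExtractNuclei:
    def test_planted_disks_recovered(self):
        amount, truth = planted_disks(seed=3)
        result = extract_nuclei(amount)
        jaccard = (result.mask & truth).sum() / (result.mask | truth).sum()
        assert jaccard >= 0.9

    def test_blank_field_empty_mask(self):
        with pytest.warns(DegenerateInputWarning):
            result = extract_nuclei(np.full((32, 32), 0.3))
        assert not result.mask.any()

    def test_invariant_to_monotone_rescaling(self):
        amount, _ = planted_disks(shape=(128, 128), seed=5)
        a = extract_nuclei(amount).mask
        b = extract_nuclei(10.0 * amount + 2.0).mask
        np.testing.assert_array_equal(a, b)


class TestQuantize:
    def test_minmax_endpoints(self):
        img = np.array([[0.5, 1.5], [1.0, 1.25]])
        q, (lo, hi) = quantize_to_8bit(img)
        assert (lo, hi) == (0.5, 1.5)
        assert q[0, 0] == 0 and q[0, 1] == 255

    def test_constant_flagged(self):
        with pytest.warns(DegenerateInputWarning):
            q, _ = quantize_to_8bit(np.full((3, 3), 2.0))
        assert not q.any()
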