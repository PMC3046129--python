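import itertools

import numpy as np
import pytest
from scipy import stats

from histoseg.mrf import (
    MRFConfig,
    clique_potential,
    gibbs_conditional,
    local_energy,
    merge_non_tumour,
    ml_labelling,
    relax_gibbs,
    relax_icm,
    relax_metropolis,
    relax_mmd,
    singleton_energy,
    total_energy,
)
from histoseg.texture import ClassModel

COLD = dict(t0=1e-3, cooling=0.5, max_sweeps=50)


def brute_force_minimum(features, model, config):
    """Exhaustive enumeration of every labelling (tiny rasters only)."""
    shape = features.shape
    best, best_u = None, np.inf
    for combo in itertools.product(range(model.n_classes), repeat=features.size):
        labels = np.array(combo).reshape(shape)
        u = sum(
            float(singleton_energy(features[i, j], labels[i, j], model))
            for i in range(shape[0])
            for j in range(shape[1])
        )
        for i in range(shape[0]):
            for j in range(shape[1]):
                for di, dj in config.offsets:
                    ni, nj = i + di, j + dj
                    if 0 <= ni < shape[0] and 0 <= nj < shape[1] and (ni, nj) > (i, j):
                        u += float(clique_potential(labels[i, j], labels[ni, nj], config.beta))
        if u < best_u:
            best, best_u = labels, u
    return best, best_u


class TestSingletonEnergy:
    def test_at_the_mean_only_constant_terms(self, two_class_model):
        e = singleton_energy(60.0, 0, two_class_model)
        assert e == pytest.approx(0.5 * np.log(2 * np.pi * 225.0))

    def test_unit_density_point_is_zero(self):
        model = ClassModel(("a", "b"), np.array([5.0, 9.0]), np.array([1 / (2 * np.pi)] * 2))
        assert singleton_energy(5.0, 0, model) == pytest.approx(0.0, abs=1e-12)

    def test_equals_negative_normal_logpdf(self, rng):
        f = rng.uniform(0, 255, 200)
        mu = rng.uniform(0, 255, 200)
        var = rng.uniform(0.5, 900, 200)
        model_e = np.array(
            [
                singleton_energy(fi, 0, ClassModel(("a", "b"), np.array([m, 0.0]), np.array([v, 1.0])))
                for fi, m, v in zip(f, mu, var)
            ]
        )
        oracle = -stats.norm.logpdf(f, loc=mu, scale=np.sqrt(var))
        np.testing.assert_allclose(model_e, oracle, rtol=1e-12)


class TestCliquePotential:
    @pytest.mark.parametrize(
        "a, b, beta, expected",
        [(1, 1, 0.9, -0.9), (1, 2, 0.9, 0.9), (0, 3, 0.0, 0.0), (2, 2, 0.0, 0.0)],
    )
    def test_potts_values(self, a, b, beta, expected):
        assert clique_potential(a, b, beta) == expected


class TestEnergies:
    def test_isolated_site_local_equals_singleton(self, two_class_model):
        f = np.array([[100.0]])
        labels = np.array([[0]])
        cfg = MRFConfig(seed=0)
        e = local_energy((0, 0), 1, labels, f, two_class_model, cfg)
        assert e == pytest.approx(float(singleton_energy(100.0, 1, two_class_model)))

    def test_uniform_neighbours_shift_by_eight_beta(self, two_class_model):
        f = np.full((3, 3), 60.0)
        labels = np.zeros((3, 3), dtype=int)
        cfg = MRFConfig(beta=0.9, seed=0)
        e = local_energy((1, 1), 0, labels, f, two_class_model, cfg)
        s = float(singleton_energy(60.0, 0, two_class_model))
        assert e == pytest.approx(s - 8 * 0.9)

    def test_two_site_total(self, two_class_model):
        f = np.array([[60.0, 60.0]])
        labels = np.zeros((1, 2), dtype=int)
        cfg = MRFConfig(beta=0.9, seed=0)
        s = float(singleton_energy(60.0, 0, two_class_model))
        assert total_energy(labels, f, two_class_model, cfg) == pytest.approx(2 * s - 0.9)

    def test_beta_zero_total_is_singleton_sum(self, rng, four_class_model):
        f = rng.uniform(0, 255, (4, 4))
        labels = rng.integers(0, 4, (4, 4))
        cfg = MRFConfig(beta=0.0, seed=0)
        expected = sum(
            float(singleton_energy(f[i, j], labels[i, j], four_class_model))
            for i in range(4)
            for j in range(4)
        )
        assert total_energy(labels, f, four_class_model, cfg) == pytest.approx(expected)

    @pytest.mark.parametrize("neighborhood", [4, 8])
    def test_total_matches_enumeration_on_2x2(self, rng, four_class_model, neighborhood):
        cfg = MRFConfig(beta=0.9, neighborhood=neighborhood, seed=0)
        f = rng.uniform(0, 255, (2, 2))
        for combo in itertools.product(range(4), repeat=4):
            labels = np.array(combo).reshape(2, 2)
            u_direct = sum(
                float(singleton_energy(f[i, j], labels[i, j], four_class_model))
                for i in range(2)
                for j in range(2)
            )
            pairs = [((0, 0), (0, 1)), ((0, 0), (1, 0)), ((0, 1), (1, 1)), ((1, 0), (1, 1))]
            if neighborhood == 8:
                pairs += [((0, 0), (1, 1)), ((0, 1), (1, 0))]
            for (a, b) in pairs:
                u_direct += float(clique_potential(labels[a], labels[b], 0.9))
            assert total_energy(labels, f, four_class_model, cfg) == pytest.approx(u_direct)

    def test_local_energy_equals_global_difference(self, rng, four_class_model):
        cfg = MRFConfig(beta=0.9, seed=0)
        f = rng.uniform(0, 255, (5, 5))
        labels = rng.integers(0, 4, (5, 5))
        for _ in range(20):
            i, j = rng.integers(0, 5, 2)
            a, b = rng.integers(0, 4, 2)
            labels[i, j] = a
            ua = total_energy(labels, f, four_class_model, cfg)
            la = local_energy((i, j), a, labels, f, four_class_model, cfg)
            labels[i, j] = b
            ub = total_energy(labels, f, four_class_model, cfg)
            lb = local_energy((i, j), b, labels, f, four_class_model, cfg)
            assert ub - ua == pytest.approx(lb - la, abs=1e-9)


RELAXERS = {
    "metropolis": relax_metropolis,
    "icm": relax_icm,
    "mmd": relax_mmd,
    "gibbs": relax_gibbs,
}


class TestRelaxers:
    @pytest.mark.parametrize("name", list(RELAXERS))
    def test_beta_zero_recovers_ml_labelling(self, rng, four_class_model, name):
        f = rng.uniform(0, 255, (16, 16))
        cfg = MRFConfig(beta=0.0, seed=3, **COLD)
        labels, _ = RELAXERS[name](f, four_class_model, cfg)
        np.testing.assert_array_equal(labels, ml_labelling(f, four_class_model))

    @pytest.mark.parametrize("name", list(RELAXERS))
    def test_two_class_planted_recovery(self, rng, two_class_model, name):
        truth = np.zeros((48, 48), dtype=int)
        truth[:, 24:] = 1
        f = np.clip(
            rng.normal(np.where(truth == 0, 60.0, 180.0), 15.0), 0, 255
        )
        cfg = MRFConfig(beta=0.9, seed=11, max_sweeps=400)
        labels, _ = RELAXERS[name](f, two_class_model, cfg)
        assert (labels == truth).mean() >= 0.99

    def test_icm_energy_monotone_non_increasing(self, rng, four_class_model):
        f = rng.uniform(0, 255, (12, 12))
        cfg = MRFConfig(beta=0.9, seed=0)
        _, trace = relax_icm(f, four_class_model, cfg)
        energies = [trace.initial_energy] + trace.energy
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_icm_fixed_point_one_flip_stable(self, rng, four_class_model):
        f = rng.uniform(0, 255, (3, 3))
        cfg = MRFConfig(beta=0.9, seed=0)
        labels, _ = relax_icm(f, four_class_model, cfg)
        u0 = total_energy(labels, f, four_class_model, cfg)
        for i in range(3):
            for j in range(3):
                for lam in range(4):
                    if lam == labels[i, j]:
                        continue
                    flipped = labels.copy()
                    flipped[i, j] = lam
                    assert total_energy(flipped, f, four_class_model, cfg) >= u0 - 1e-9

    def test_icm_matches_global_minimum_on_tiny_instance(self, rng, four_class_model):
        # 2x2 instances are small enough for exhaustive enumeration; with
        # well-separated likelihoods ICM lands on the global MAP labelling.
        cfg = MRFConfig(beta=0.9, seed=0)
        f = np.array([[45.0, 95.0], [165.0, 225.0]])
        labels, _ = relax_icm(f, four_class_model, cfg)
        expected, _ = brute_force_minimum(f, four_class_model, cfg)
        np.testing.assert_array_equal(labels, expected)

    def test_metropolis_final_energy_not_above_initial(self, rng, four_class_model):
        f = rng.uniform(0, 255, (24, 24))
        cfg = MRFConfig(beta=0.9, seed=5, max_sweeps=200)
        labels, trace = relax_metropolis(f, four_class_model, cfg)
        assert total_energy(labels, f, four_class_model, cfg) <= trace.initial_energy + 1e-9

    def test_metropolis_bit_reproducible(self, rng, four_class_model):
        f = rng.uniform(0, 255, (20, 20))
        cfg = MRFConfig(beta=0.9, seed=42, max_sweeps=100)
        with pytest.warns(UserWarning, match="did not converge"):
            a, ta = relax_metropolis(f, four_class_model, cfg)
        with pytest.warns(UserWarning, match="did not converge"):
            b, tb = relax_metropolis(f, four_class_model, cfg)
        np.testing.assert_array_equal(a, b)
        assert ta.energy == tb.energy

    def test_gibbs_conditional_normalized(self, rng, four_class_model):
        f = rng.uniform(0, 255, (4, 4))
        labels = rng.integers(0, 4, (4, 4))
        cfg = MRFConfig(beta=0.9, seed=0)
        for t in (0.5, 2.0, 4.0):
            p = gibbs_conditional((1, 2), labels, f, four_class_model, cfg, t)
            assert p.sum() == pytest.approx(1.0)
            assert np.all(p >= 0)


class TestMergeNonTumour:
    def test_all_stroma_becomes_non_tumour(self):
        labels = np.full((3, 3), 1)
        np.testing.assert_array_equal(merge_non_tumour(labels), 1)

    def test_tumour_count_conserved(self, rng):
        labels = rng.integers(0, 4, (10, 10))
        merged = merge_non_tumour(labels)
        assert (merged == 0).sum() == (labels == 0).sum()
        assert (merged == 2).sum() == (labels == 3).sum()

    def test_histogram_bins_sum(self, rng):
        labels = rng.integers(0, 4, (20, 20))
        merged = merge_non_tumour(labels)
        hist4 = np.bincount(labels.ravel(), minlength=4)
        hist3 = np.bincount(merged.ravel(), minlength=3)
        assert hist3[1] == hist4[1] + hist4[2]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            merge_non_tumour(np.array([[5]]))
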