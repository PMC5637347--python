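"""Differential-unit selection, pruning, gene energies and ranking."""

import numpy as np
import pytest

import srbmrank as sr
import srbmrank.ranking as rk
from srbmrank.rbm import BB, GB, RBMParameters, TrainingConfig
from srbmrank.srbm import ActivationProfile, SRBMModel, TrainingTrace


def make_model(W1, B1, C1, W2=None, B2=None, C2=None):
    rbm1 = RBMParameters(W1, B1, C1, GB)
    rbm2 = None
    if W2 is not None:
        rbm2 = RBMParameters(W2, B2, C2, BB)
    cfg = TrainingConfig(epochs=0)
    return SRBMModel(rbm1, rbm2, TrainingTrace(), TrainingTrace(), cfg, cfg)


class TestSelection:
    def test_differential_activation_symmetric_and_absolute(self):
        a = ActivationProfile(np.array([8, 0]), np.array([3]), 8)
        b = ActivationProfile(np.array([0, 8]), np.array([3]), 8)
        d1, d2 = rk.differential_activation(a, b)
        np.testing.assert_array_equal(d1, [8, 8])
        np.testing.assert_array_equal(d2, [0])
        d1r, _ = rk.differential_activation(b, a)
        np.testing.assert_array_equal(d1, d1r)

    def test_size_mismatch_rejected(self):
        a = ActivationProfile(np.array([1, 2]), np.array([1]), 8)
        b = ActivationProfile(np.array([1]), np.array([1]), 8)
        with pytest.raises(ValueError, match="layer sizes"):
            rk.differential_activation(a, b)

    def test_default_thresholds(self):
        sel = rk.select_neurons(np.array([5, 0]), np.array([8, 2]))
        assert (sel.layer1_threshold, sel.layer2_threshold) == (1, 5)

    def test_strictly_larger_than_threshold(self):
        sel = rk.select_neurons(np.array([0, 1, 2, 3]), np.array([]), t1=1)
        np.testing.assert_array_equal(sel.layer1_selected, [2, 3])

    def test_threshold_at_maximum_empties_selection(self):
        diff = np.array([2, 4, 1])
        with pytest.warns(UserWarning, match="empty layer-1"):
            sel = rk.select_neurons(diff, np.array([9]), t1=4, t2=5)
        assert sel.layer1_selected.size == 0


class TestPruning:
    def test_zero_fraction_is_identity(self, small_gb):
        out = rk.prune_weak_connections(small_gb, 0.0)
        np.testing.assert_array_equal(out.W, small_gb.W)

    def test_weakest_third_of_fanout_zeroed(self):
        # one visible unit fanning out to three hidden units
        p = RBMParameters(np.array([[3.0], [-1.0], [0.5]]), np.zeros(1),
                          np.zeros(3), BB)
        out = rk.prune_weak_connections(p, 1.0 / 3.0)
        np.testing.assert_array_equal(out.W.ravel(), [3.0, -1.0, 0.0])

    def test_pruned_count_per_unit(self):
        rng = np.random.default_rng(0)
        p = RBMParameters(rng.normal(size=(9, 5)), np.zeros(5), np.zeros(9),
                          BB)
        out = rk.prune_weak_connections(p, 1.0 / 3.0)
        zeros_per_visible = (out.W == 0).sum(axis=0)
        np.testing.assert_array_equal(zeros_per_visible, 3)  # floor(9/3)

    def test_tie_prunes_lower_index_first(self):
        p = RBMParameters(np.array([[1.0], [1.0], [2.0]]), np.zeros(1),
                          np.zeros(3), BB)
        out = rk.prune_weak_connections(p, 1.0 / 3.0)
        np.testing.assert_array_equal(out.W.ravel(), [0.0, 1.0, 2.0])

    def test_prunes_both_layers_of_a_stack(self):
        model = make_model(np.ones((3, 2)), np.zeros(2), np.zeros(3),
                           np.ones((3, 3)), np.zeros(3), np.zeros(3))
        out = rk.prune_weak_connections(model, 1.0 / 3.0)
        assert (out.rbm1.W == 0).sum() == 2
        assert (out.rbm2.W == 0).sum() == 3


class TestGeneEnergy:
    def test_zero_everything_gives_zero(self):
        model = make_model(np.zeros((2, 2)), np.zeros(2), np.zeros(2),
                           np.zeros((1, 2)), np.zeros(2), np.zeros(1))
        sel = rk.NeuronSelection(np.array([0, 1]), np.array([0]))
        E = rk.gene_energy(model, np.zeros(2), sel)
        np.testing.assert_allclose(E, 0.0)

    def test_hand_built_circuit(self):
        """2 genes -> 2 hidden -> 1 output with chosen weights; all four
        energy terms evaluated by hand."""
        W1 = np.array([[2.0, -1.0], [0.5, 0.5]])
        B1 = np.array([0.1, -0.2])
        C1 = np.zeros(2)
        W2 = np.array([[1.5, -0.5]])
        B2 = np.array([0.3, 0.4])
        C2 = np.zeros(1)
        model = make_model(W1, B1, C1, W2, B2, C2)
        v = np.array([1.0, 0.5])
        sel = rk.NeuronSelection(np.array([0, 1]), np.array([0]))
        # propagation: logits1 = W1 @ v = (1.5, 0.75) -> h1 = (1, 1)
        # logits2 = W2 @ h1 = 1.0 -> h2 = (1)
        # E_g = (v_g - b1_g)^2/2 - v_g * sum_j h1_j W1[j, g]
        #       - sum_i B2_i v2_i - sum_ij h2_j W2[j, i] v2_i   (shared)
        shared = -(0.3 + 0.4) - (1.5 - 0.5)
        e0 = 0.5 * (1.0 - 0.1) ** 2 - 1.0 * (2.0 + 0.5) + shared
        e1 = 0.5 * (0.5 + 0.2) ** 2 - 0.5 * (-1.0 + 0.5) + shared
        E = rk.gene_energy(model, v, sel)
        np.testing.assert_allclose(E, [e0, e1])

    def test_empty_selection_reduces_to_quadratic_term(self):
        rng = np.random.default_rng(0)
        model = make_model(rng.normal(size=(3, 4)), rng.normal(size=4),
                           rng.normal(size=3), rng.normal(size=(2, 3)),
                           rng.normal(size=3), rng.normal(size=2))
        v = rng.normal(size=4)
        sel = rk.NeuronSelection(np.array([], dtype=int),
                                 np.array([], dtype=int))
        E = rk.gene_energy(model, v, sel)
        np.testing.assert_allclose(E, 0.5 * (v - model.rbm1.B) ** 2)

    def test_out_of_range_selection_rejected(self):
        model = make_model(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError, match="out of range"):
            rk.gene_energy(model, np.zeros(2),
                           rk.NeuronSelection(np.array([5]),
                                              np.array([], dtype=int)))

    def test_adding_never_active_units_changes_nothing(self):
        # unit 1 has a huge negative bias: never activates
        model = make_model(np.array([[1.0, -0.5], [0.2, 0.3]]),
                           np.zeros(2), np.array([0.0, -50.0]))
        v = np.array([0.7, -0.7])
        small = rk.NeuronSelection(np.array([0]), np.array([], dtype=int))
        large = rk.NeuronSelection(np.array([0, 1]), np.array([], dtype=int))
        np.testing.assert_allclose(rk.gene_energy(model, v, small),
                                   rk.gene_energy(model, v, large))


class TestEnergyChange:
    def test_equal_periods_give_zero(self):
        E = np.random.default_rng(0).normal(size=(5, 3))
        np.testing.assert_allclose(rk.energy_change(E, E), 0.0)

    def test_hand_means(self):
        E1 = np.array([[2.0, 4.0]])  # mean 3
        E2 = np.array([[1.0, 1.0]])  # mean 1
        np.testing.assert_allclose(rk.energy_change(E1, E2), [2.0])

    def test_period_swap_invariance_and_nonnegativity(self):
        rng = np.random.default_rng(1)
        E1, E2 = rng.normal(size=(6, 4)), rng.normal(size=(6, 3))
        C = rk.energy_change(E1, E2)
        np.testing.assert_allclose(C, rk.energy_change(E2, E1))
        assert (C >= 0).all()

    def test_shared_offset_invariance(self):
        rng = np.random.default_rng(2)
        E1, E2 = rng.normal(size=(6, 4)), rng.normal(size=(6, 3))
        C = rk.energy_change(E1, E2)
        np.testing.assert_allclose(C, rk.energy_change(E1 + 3.7, E2 + 3.7),
                                   atol=1e-12)

    def test_centering_removes_per_sample_offsets(self):
        rng = np.random.default_rng(3)
        E1, E2 = rng.normal(size=(6, 4)), rng.normal(size=(6, 3))
        offset1 = rng.normal(scale=50, size=(1, 4))
        offset2 = rng.normal(scale=50, size=(1, 3))
        np.testing.assert_allclose(
            rk.energy_change(E1, E2, center=True),
            rk.energy_change(E1 + offset1, E2 + offset2, center=True),
            atol=1e-9)

    def test_empty_period_rejected(self):
        with pytest.raises(ValueError, match="at least one sample"):
            rk.energy_change(np.empty((3, 0)), np.ones((3, 2)))


class TestRankGenes:
    def test_sort_oracle(self):
        table = rk.rank_genes(np.array([0.1, 5.0, 2.0]), ["g1", "g2", "g3"])
        assert table.ranked_gene_ids() == ["g2", "g3", "g1"]

    def test_ties_keep_input_order(self):
        table = rk.rank_genes(np.array([1.0, 1.0, 1.0]), ["a", "b", "c"])
        assert table.ranked_gene_ids() == ["a", "b", "c"]

    def test_permutation_equivariance(self):
        C = np.array([0.3, 2.0, 1.1, 0.7])
        genes = ["a", "b", "c", "d"]
        base = rk.rank_genes(C, genes).ranked_gene_ids()
        perm = [2, 0, 3, 1]
        shuffled = rk.rank_genes(C[perm],
                                 [genes[i] for i in perm]).ranked_gene_ids()
        assert base == shuffled

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            rk.rank_genes(np.array([1.0, np.nan]), ["a", "b"])


class TestRunVariant:
    def test_rbm_ii_on_identical_periods_gives_zero_changes(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(40, 8))
        m1 = sr.ExpressionMatrix([f"g{i}" for i in range(40)],
                                 [f"a{j}" for j in range(8)], values)
        m2 = sr.ExpressionMatrix([f"g{i}" for i in range(40)],
                                 [f"b{j}" for j in range(8)], values)
        cfg = TrainingConfig(eta=0.02, epochs=5, seed=0,
                             mean_gradient=True)
        table = rk.run_variant(m1, m2, "RBM-II", cfg, cfg, 8, 0, seed=0)
        np.testing.assert_allclose(table.C, 0.0, atol=1e-9)

    def test_variant_coincidence_without_pruning_or_selection(self,
                                                              easy_fit):
        """With no pruning and every unit selected, the I- and II-style
        energies agree."""
        model = easy_fit.run.models[0]
        all_units = rk.NeuronSelection.all_units(model.n_hidden1,
                                                 model.n_hidden2)
        v = np.random.default_rng(0).normal(size=model.n_visible)
        pruned = rk.prune_weak_connections(model, 0.0)
        np.testing.assert_allclose(rk.gene_energy(model, v, all_units),
                                   rk.gene_energy(pruned, v, all_units))

    def test_sample_reorder_invariance(self, easy_fit):
        """Reordering samples within a period leaves the ranking
        unchanged (the change uses per-period means only)."""
        E1, E2 = easy_fit.ranking.E1, easy_fit.ranking.E2
        genes = easy_fit.ranking.gene_ids
        rng = np.random.default_rng(0)
        base = rk.rank_genes(rk.energy_change(E1, E2, center=True), genes)
        perm = rk.rank_genes(
            rk.energy_change(E1[:, rng.permutation(E1.shape[1])],
                             E2[:, rng.permutation(E2.shape[1])],
                             center=True),
            genes)
        assert base.ranked_gene_ids() == perm.ranked_gene_ids()

    def test_recovers_planted_genes_above_chance(self, easy_fit,
                                                 easy_dataset):
        result = easy_fit.evaluate(easy_dataset.labels)
        assert result.auc > 0.5

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            rk.VariantSpec(name="SRBM-III")

    def test_per_period_regime_runs(self, easy_dataset):
        cfg1 = TrainingConfig(eta=0.02, epochs=3, seed=0,
                              mean_gradient=True)
        cfg2 = TrainingConfig(eta=0.5, epochs=5, seed=1, mean_gradient=True)
        table = rk.run_variant(easy_dataset.period1, easy_dataset.period2,
                               "SRBM-II", cfg1, cfg2, 20, 5, seed=0,
                               regime="per-period")
        assert len(table.gene_ids) == easy_dataset.period1.n_genes
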