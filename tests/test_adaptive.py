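import numpy as np
import pytest

from amda import GroupLabels, amda_test, permute_labels
from amda.simdata import SimulationScenario, generate_dataset
from reference import amda_reference


def _small_dataset(seed, p=6, n=12, null=True):
    sc = SimulationScenario(p=p, n=n, sparsity=0.5, null_model=null, seed=seed)
    table, labels, _ = generate_dataset(sc)
    return table, labels


class TestAgainstReference:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_literal_stepwise_procedure(self, seed):
        """The batched engine reproduces the one-permutation-at-a-time
        procedure (scipy KS per column, literal decoy matrices, explicit
        double-sum MMD) exactly: same subset, statistics and p-value."""
        table, labels = _small_dataset(seed, null=(seed % 2 == 0))
        B = 60
        res = amda_test(table, labels, B=B, seed=seed, keep_permutation_stats=True)
        stat, pv, S, perm_stats = amda_reference(table.values, labels.labels,
                                                 B, seed)
        assert sorted(res.selection.selected) == sorted(int(j) for j in S)
        assert res.statistic == pytest.approx(stat, rel=1e-10, abs=1e-12)
        np.testing.assert_allclose(res.permutation_stats, perm_stats,
                                   rtol=1e-10, atol=1e-12)
        assert res.p_value == pv

    def test_frozen_subset_ablation_matches_reference(self):
        table, labels = _small_dataset(9)
        res = amda_test(table, labels, B=40, seed=4,
                        reselect_per_permutation=False,
                        keep_permutation_stats=True)
        stat, pv, S, perm_stats = amda_reference(table.values, labels.labels,
                                                 40, 4, reselect=False)
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        np.testing.assert_allclose(res.permutation_stats, perm_stats, rtol=1e-10)
        assert res.p_value == pv


class TestBehaviour:
    def test_deterministic_under_fixed_seed(self):
        table, labels = _small_dataset(5, p=5, n=10)
        a = amda_test(table, labels, B=100, seed=42, keep_permutation_stats=True)
        b = amda_test(table, labels, B=100, seed=42, keep_permutation_stats=True)
        assert a.statistic == b.statistic
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.permutation_stats, b.permutation_stats)

    def test_constant_table_selects_nothing_and_never_rejects(self):
        table = np.ones((8, 4))
        labels = GroupLabels(np.repeat([1, 2], 4))
        res = amda_test(table, labels, B=50, seed=0)
        assert res.statistic == 0.0
        assert res.selected_taxa == ()
        assert res.p_value == 1.0  # every permuted statistic is >= 0

    def test_selected_taxa_are_named_and_reported_with_pvalues(self):
        table, labels = _small_dataset(2, null=False)
        res = amda_test(table, labels, B=30, seed=1)
        assert all(t in table.taxa_ids for t in res.selected_taxa)
        sel = res.selection
        assert sel.pvals_real.shape == (table.n_taxa,)
        assert all(sel.pvals_real[j] < sel.pvals_decoy[j] for j in sel.selected)
        payload = res.to_dict()
        assert payload["p_value"] == res.p_value
        assert payload["selection"]["taxa"] == list(res.selected_taxa)

    def test_add_one_convention(self):
        table, labels = _small_dataset(7)
        plain = amda_test(table, labels, B=50, seed=3, keep_permutation_stats=True)
        shifted = amda_test(table, labels, B=50, seed=3, add_one=True)
        count = int((plain.permutation_stats >= plain.statistic).sum())
        assert shifted.p_value == pytest.approx((1 + count) / 51)

    def test_input_validation(self):
        table, labels = _small_dataset(1)
        with pytest.raises(ValueError):
            amda_test(table, labels, B=0, seed=0)
        bad = GroupLabels(np.array([1] + [2] * (labels.n - 1)))
        with pytest.raises(ValueError):
            amda_test(table, bad, B=10, seed=0)
        with pytest.raises(ValueError):
            amda_test(table, np.repeat([1, 2], 3), B=10, seed=0)  # length mismatch


class TestPower:
    def test_rejection_rate_monotone_in_effect_size(self):
        """Power grows with the magnitude of the mean shifts at fixed
        (n, p, sparsity)."""
        rates = []
        reps = 120
        for scale in (0.0, 1.0, 3.0):
            rej = 0
            for i in range(reps):
                sc = SimulationScenario(
                    p=20, n=40, sparsity=0.5, seed=500 + i,
                    null_model=(scale == 0.0),
                    effect_low=-0.5 * scale, effect_high=0.5 * scale)
                table, y, _ = generate_dataset(sc)
                rej += amda_test(table, y, B=200, seed=900 + i).p_value <= 0.05
            rates.append(rej / reps)
        se = np.sqrt(0.25 / reps)
        assert rates[1] >= rates[0] - 2 * se
        assert rates[2] >= rates[1] - 2 * se
        assert rates[2] > rates[0] + 4 * se  # strict gain at the strong end


class TestPermuteLabels:
    def test_group_sizes_conserved(self, rng):
        y = GroupLabels(np.array([1] * 7 + [2] * 5))
        for _ in range(20):
            out = permute_labels(y, rng)
            assert (out.n1, out.n2) == (7, 5)

    def test_position_marginals_uniform(self):
        rng = np.random.default_rng(8)
        y = GroupLabels(np.repeat([1, 2], [3, 9]))
        draws = 2000
        freq = np.zeros(12)
        for _ in range(draws):
            freq += permute_labels(y, rng).labels == 1
        freq /= draws
        se = np.sqrt(0.25 / draws) * 4
        assert np.all(np.abs(freq - 3 / 12) < 4 * se + 0.02)

    def test_identity_draw(self):
        class IdentityRng:
            def permutation(self, n):
                return np.arange(n)

        y = GroupLabels(np.array([1, 2, 1, 2]))
        np.testing.assert_array_equal(permute_labels(y, IdentityRng()).labels,
                                      y.labels)
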