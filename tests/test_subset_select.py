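import numpy as np
import pytest
from scipy import stats

from amda import (GroupLabels, clr, make_decoy, marginal_pvalues, select_subset,
                  to_composition)
from reference import ks_pvalues_reference


class TestMakeDecoy:
    def test_preserves_row_multiset_and_column_stats(self, random_clr, rng):
        decoy = make_decoy(random_clr, rng)
        a = np.sort(random_clr.values, axis=0)
        b = np.sort(decoy.values, axis=0)
        np.testing.assert_array_equal(a, b)
        # means agree up to summation reassociation only
        np.testing.assert_allclose(decoy.values.mean(axis=0),
                                   random_clr.values.mean(axis=0),
                                   rtol=0, atol=1e-14)

    def test_identity_permutation_returns_input(self, random_clr):
        class IdentityRng:
            def permutation(self, n):
                return np.arange(n)

        decoy = make_decoy(random_clr, IdentityRng())
        np.testing.assert_array_equal(decoy.values, random_clr.values)

    def test_rows_stay_intact(self, random_clr, rng):
        decoy = make_decoy(random_clr.values, rng)
        orig = {tuple(r) for r in random_clr.values}
        assert {tuple(r) for r in decoy} == orig


class TestMarginalPvalues:
    def test_constant_column_gets_p_one(self, rng):
        Z = rng.normal(size=(10, 3))
        Z[:, 1] = 4.2
        y = np.repeat([1, 2], 5)
        p = marginal_pvalues(Z, y)
        assert p[1] == 1.0

    def test_matches_scipy_per_column(self, rng):
        Z = rng.normal(size=(14, 6))
        Z[:7, 0] += 2.0
        y = np.array([1] * 7 + [2] * 7)
        np.testing.assert_allclose(marginal_pvalues(Z, y, mode="exact"),
                                   ks_pvalues_reference(Z, y, "exact"),
                                   atol=1e-12)
        np.testing.assert_allclose(marginal_pvalues(Z, y, mode="asymp"),
                                   ks_pvalues_reference(Z, y, "asymp"),
                                   atol=1e-10)

    def test_separated_groups_reach_minimal_pvalue(self):
        Z = np.array([[1.0], [2.0], [3.0], [10.0], [20.0], [30.0]])
        y = np.array([1, 1, 1, 2, 2, 2])
        assert marginal_pvalues(Z, y, mode="exact")[0] == pytest.approx(0.1)

    def test_null_pvalues_uniform_at_attainable_levels(self):
        # exact KS p-values are discrete, so uniformity means
        # P(p <= c) = c exactly at every attainable level c
        rng = np.random.default_rng(99)
        n1 = n2 = 25
        y = np.repeat([1, 2], n1)
        reps = 800
        pvals = np.array([
            marginal_pvalues(rng.normal(size=(n1 + n2, 1)), y)[0]
            for _ in range(reps)
        ])
        for c in np.unique(pvals):
            se = np.sqrt(max(c * (1 - c), 1e-6) / reps)
            assert abs((pvals <= c).mean() - c) < 4 * se + 1e-9


class TestSelectSubset:
    def test_extreme_shift_always_selected(self, rng):
        n1 = n2 = 10
        y = GroupLabels(np.repeat([1, 2], n1))
        hits = 0
        draws = 400
        for d in range(draws):
            Z = rng.normal(size=(n1 + n2, 5))
            Z[:n1, 2] += 10.0  # ~10 sigma shift
            sel = select_subset(Z, y, rng)
            hits += 2 in sel.selected
        assert hits / draws > 0.99

    def test_all_ties_select_nothing(self):
        # n = 2: either decoy permutation reproduces the same two rows, so
        # every real/decoy p-value pair ties and strict < selects nothing.
        Z = clr(to_composition(np.array([[1.0, 3.0], [3.0, 1.0]])))
        y = GroupLabels(np.array([1, 2]))
        for seed in range(10):
            sel = select_subset(Z, y, seed)
            assert sel.selected == ()
            np.testing.assert_array_equal(sel.pvals_real, sel.pvals_decoy)

    def test_null_selection_frequency_near_half_among_untied(self, rng):
        # under H0 real and decoy p-values are exchangeable, so a column is
        # selected with probability 1/2 *given* that the pair is not tied
        # (exact small-sample p-values tie often)
        n1 = n2 = 15
        y = GroupLabels(np.repeat([1, 2], n1))
        p = 8
        selected = untied = 0
        draws = 300
        for _ in range(draws):
            Z = rng.normal(size=(n1 + n2, p))
            sel = select_subset(Z, y, rng)
            selected += sel.size
            untied += int((sel.pvals_real != sel.pvals_decoy).sum())
        freq = selected / untied
        se = np.sqrt(0.25 / untied)
        assert abs(freq - 0.5) < 4 * se

    def test_selection_probability_monotone_in_effect(self, rng):
        n1 = n2 = 15
        y = GroupLabels(np.repeat([1, 2], n1))
        freqs = []
        for shift in (0.0, 0.8, 2.0):
            hits = 0
            draws = 250
            for _ in range(draws):
                Z = rng.normal(size=(n1 + n2, 4))
                Z[:n1, 0] += shift
                hits += 0 in select_subset(Z, y, rng).selected
            freqs.append(hits / draws)
        assert freqs[0] < freqs[1] < freqs[2]

    def test_records_decoy_seed(self, random_clr):
        y = GroupLabels(np.repeat([1, 2], 6))
        sel = select_subset(random_clr, y, 123)
        assert sel.decoy_seed == 123
        sel2 = select_subset(random_clr, y, 123)
        assert sel.selected == sel2.selected
        np.testing.assert_array_equal(sel.decoy_permutation, sel2.decoy_permutation)
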