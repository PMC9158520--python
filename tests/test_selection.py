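"""GY94 codon model: back-translation, rates, pruning likelihood, LRT."""

import numpy as np
import pytest
from scipy.stats import chi2

from plastome.selection import (BranchModelFit, CodonAlignment, IndexedTree,
                                back_translate, empirical_f3x4, f3x4,
                                fit_branch_model, genetic_code, gy94_rates,
                                log_likelihood, lrt)
from plastome.selection import _eigensystem, _transition_matrix
from plastome.synthetic import simulate_codon_alignment


class TestBackTranslate:
    def test_simple_two_codons(self):
        caln = back_translate({"x": "MA"}, {"x": "ATGGCT"})
        assert caln.rows() == [("x", "ATGGCT")]

    def test_gap_expansion(self):
        caln = back_translate({"x": "M-A", "y": "MKA"},
                              {"x": "ATGGCT", "y": "ATGAAAGCT"})
        assert dict(caln.rows())["x"] == "ATG---GCT"

    def test_terminal_stop_stripped(self):
        caln = back_translate({"x": "MA"}, {"x": "ATGGCTTAA"})
        assert caln.rows() == [("x", "ATGGCT")]

    def test_mismatch_error_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            back_translate({"x": "MV"}, {"x": "ATGGCA"})

    def test_length_not_divisible_by_three(self):
        with pytest.raises(ValueError, match="divisible"):
            back_translate({"x": "MA"}, {"x": "ATGGC"})


class TestFrequencies:
    def test_uniform_positions_give_uniform_codons(self):
        freqs = f3x4(np.full((3, 4), 0.25))
        assert np.allclose(freqs.pi, 1 / 61)

    def test_frequencies_sum_to_one(self, skewed_freqs):
        assert skewed_freqs.pi.sum() == pytest.approx(1.0)
        assert np.all(skewed_freqs.pi > 0)

    def test_empirical_f3x4_recovers_composition(self):
        code = genetic_code()
        rows = ["ATGGCTGCA" * 30]
        caln = CodonAlignment.from_dna_rows(["x"], rows)
        freqs = empirical_f3x4(caln)
        # codons absent from the data still get positive F3x4 mass
        assert np.all(freqs.pi >= 0) and freqs.pi.sum() == pytest.approx(1)
        top = code.codons[int(np.argmax(freqs.pi))]
        assert top[0] in "AG"  # dominated by the observed positional mix


class TestGY94Rates:
    def test_time_reversibility(self, skewed_freqs):
        q = gy94_rates(3.0, 0.4, skewed_freqs)
        flux = skewed_freqs.pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_omega_zero_silences_nonsynonymous(self, skewed_freqs):
        code = skewed_freqs.code
        q = gy94_rates(2.0, 0.0, skewed_freqs)
        assert np.all(q[code.pair_i[code.pair_ns],
                        code.pair_j[code.pair_ns]] == 0)

    def test_multi_nucleotide_changes_forbidden(self, skewed_freqs):
        code = skewed_freqs.code
        q = gy94_rates(2.0, 0.5, skewed_freqs)
        single = set(zip(code.pair_i.tolist(), code.pair_j.tolist()))
        for i in range(0, 61, 7):
            for j in range(0, 61, 11):
                if i != j and (i, j) not in single:
                    assert q[i, j] == 0

    def test_mean_rate_scaled_to_one(self, skewed_freqs):
        q = gy94_rates(2.0, 0.5, skewed_freqs)
        assert -(skewed_freqs.pi * np.diag(q)).sum() == pytest.approx(1.0)

    def test_degenerate_frequencies_rejected(self):
        from plastome.selection import CodonFrequencies

        pi = np.zeros(61)
        pi[0] = 1.0
        with pytest.raises(ValueError):
            gy94_rates(2.0, 0.5, CodonFrequencies(pi))


class TestLikelihood:
    def test_zero_branch_lengths_closed_form(self, skewed_freqs):
        tree = "(a:0.0,b:0.0,c:0.0);"
        caln = simulate_codon_alignment(tree, 2.0, 0.3, skewed_freqs, 40,
                                        seed=1)
        lnl = log_likelihood(caln, tree, 2.0, 0.3, skewed_freqs)
        expect = np.log(skewed_freqs.pi[caln.codons[0]]).sum()
        assert lnl == pytest.approx(expect, abs=1e-8)

    def test_pruning_equals_brute_force_star(self, skewed_freqs):
        tree = "(a:0.1,b:0.2,c:0.3);"
        caln = simulate_codon_alignment(tree, 2.0, 0.3, skewed_freqs, 3,
                                        seed=2)
        lnl = log_likelihood(caln, tree, 2.0, 0.3, skewed_freqs)
        assert lnl == pytest.approx(
            _brute_force_star(caln, {"a": 0.1, "b": 0.2, "c": 0.3},
                              2.0, 0.3, skewed_freqs), abs=1e-10)

    def test_rerooting_invariance(self, skewed_freqs):
        # the same unrooted 3-taxon tree rooted two ways (pulley principle)
        t1 = "(a:0.1,b:0.2,c:0.3);"
        t2 = "((a:0.1,b:0.2):0.12,c:0.18);"
        caln = simulate_codon_alignment(t1, 2.0, 0.3, skewed_freqs, 60,
                                        seed=3)
        l1 = log_likelihood(caln, t1, 2.0, 0.3, skewed_freqs)
        l2 = log_likelihood(caln, t2, 2.0, 0.3, skewed_freqs)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_gap_codons_are_missing_data(self, skewed_freqs):
        tree = "(a:0.1,b:0.2);"
        caln = simulate_codon_alignment(tree, 2.0, 0.3, skewed_freqs, 10,
                                        seed=4)
        gapped = CodonAlignment(caln.ids, caln.codons.copy())
        gapped.codons[0, 0] = -1
        full = log_likelihood(caln, tree, 2.0, 0.3, skewed_freqs)
        part = log_likelihood(gapped, tree, 2.0, 0.3, skewed_freqs)
        # dropping data can only increase the per-site likelihood
        assert part > full


def _brute_force_star(caln, lengths, kappa, omega, freqs):
    """Exhaustive summation over the internal node of a 3-taxon star."""
    q = gy94_rates(kappa, omega, freqs)
    eig = _eigensystem(q, freqs.pi)
    ps = {l: _transition_matrix(eig, t) for l, t in lengths.items()}
    obs = dict(zip(caln.ids, caln.codons))
    total = 0.0
    for s in range(caln.n_codons):
        site = 0.0
        for anc in range(61):
            term = freqs.pi[anc]
            for leaf in lengths:
                term *= ps[leaf][anc, obs[leaf][s]]
            site += term
        total += np.log(site)
    return total


class TestBranchClasses:
    def test_foreground_clade_marks_stem_and_internal_branches(self):
        tree = "(((a:1,b:1):1,c:1):1,(d:1,e:1):1);"
        it = IndexedTree(tree, foreground=["a", "b"])
        fg_leaves = {it.labels[i] for i in range(it.n_nodes)
                     if it.edge_class[i] == 1 and it.labels[i]}
        assert fg_leaves == {"a", "b"}
        # the a+b ancestor's stem branch is foreground too: 3 branches total
        assert int(it.edge_class.sum()) == 3

    def test_unknown_foreground_taxon_rejected(self):
        with pytest.raises(ValueError, match="not in tree"):
            IndexedTree("(a:1,b:1,c:1);", foreground=["z"])


class TestLRT:
    def _fit(self, lnl, wb, wf, model="two_ratio"):
        return BranchModelFit(model, lnl, 2.0,
                              {"background": wb, "foreground": wf},
                              np.array([0.1]), 3)

    def test_equal_likelihoods(self):
        res = lrt(self._fit(-100.0, 0.3, 0.3, "one_ratio"),
                  self._fit(-100.0, 0.3, 0.3))
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_critical_value_of_chi2_df1(self):
        res = lrt(self._fit(-100.0, 0.3, 0.3, "one_ratio"),
                  self._fit(-100.0 + 3.841459 / 2, 0.3, 0.5))
        assert res.p_value == pytest.approx(0.05, abs=1e-4)
        assert res.p_value == pytest.approx(chi2.sf(3.841459, 1))

    def test_positive_selection_verdict(self):
        null = self._fit(-100.0, 0.3, 0.3, "one_ratio")
        alt = self._fit(-100.0 + 3.4, 0.3, 1.4)  # stat 6.8 -> p ~ 0.009
        res = lrt(null, alt)
        assert res.significant and res.positive_selection
        assert not res.fast_evolving

    def test_fast_evolving_verdict(self):
        null = self._fit(-100.0, 0.2, 0.2, "one_ratio")
        alt = self._fit(-100.0 + 3.4, 0.2, 0.8)
        res = lrt(null, alt)
        assert res.fast_evolving and not res.positive_selection

    def test_small_negative_statistic_clipped(self):
        res = lrt(self._fit(-100.0, 0.3, 0.3, "one_ratio"),
                  self._fit(-100.0001, 0.3, 0.3))
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestFitNesting:
    def test_alternative_never_below_null(self, skewed_freqs,
                                          eight_taxon_tree):
        fg = ["a", "b", "c", "d"]
        caln = simulate_codon_alignment(eight_taxon_tree, 2.0, 0.3,
                                        skewed_freqs, 150, seed=6,
                                        foreground=fg)
        null = fit_branch_model(caln, eight_taxon_tree, fg,
                                model="one_ratio", seed=0, starts=(0.5,))
        alt = fit_branch_model(caln, eight_taxon_tree, fg,
                               model="two_ratio", seed=0, starts=(),
                               init=null)
        assert alt.lnL >= null.lnL - 1e-6
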