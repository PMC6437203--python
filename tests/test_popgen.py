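import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.stats import dirichlet_multinomial

from _oracles import exhaustive_rarefaction, hand_upgma_3taxa
from seabream.io import GenotypeTable, HaplotypeAlignment
from seabream.popgen import (
    DistanceMatrix,
    _dm_loglik,
    allele_counts,
    allelic_richness,
    differentiation_test_from_table,
    eb_fst_pair,
    expected_heterozygosity,
    haplotype_diversity,
    haplotype_richness,
    nucleotide_diversity,
    permutation_differentiation_test,
    rarefied_richness,
    upgma,
)


def table_from_pairs(pairs, pop="P1", locus="L1"):
    geno = np.array(pairs, dtype=int)[:, None, :]
    ids = [f"i{k}" for k in range(len(pairs))]
    return GenotypeTable(ids, [pop] * len(pairs), [locus], geno)


class TestAlleleCounts:
    def test_simple_tabulation(self):
        t = table_from_pairs([(1, 1), (1, 2), (2, 2)])
        ft = allele_counts(t)
        assert ft.counts["L1"].loc["P1"].to_dict() == {1: 3, 2: 3}
        assert ft.sample_sizes["L1"]["P1"] == 6

    def test_missing_excluded_and_all_missing_flagged(self):
        t = table_from_pairs([(1, 1), (0, 0)])
        ft = allele_counts(t)
        assert ft.counts["L1"].loc["P1"].sum() == 2
        t2 = table_from_pairs([(0, 0), (0, 0)])
        ft2 = allele_counts(t2)
        assert ft2.counts["L1"].shape[1] == 0
        assert ft2.sample_sizes["L1"]["P1"] == 0


class TestRarefaction:
    def test_degenerate_cases(self):
        assert rarefied_richness([10], 5) == pytest.approx(1.0)
        assert rarefied_richness([4, 3, 2], 1) == pytest.approx(1.0)

    def test_small_instance_matches_enumeration_exactly(self):
        # copies (a,a,b,c), all C(4,2)=6 subsamples enumerated by hand
        counts = [2, 1, 1]
        assert rarefied_richness(counts, 2) == pytest.approx(
            exhaustive_rarefaction(counts, 2), abs=1e-12
        )

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=5).filter(
            lambda c: sum(c) >= 2
        ),
        st.data(),
    )
    def test_formula_equals_exhaustive_oracle(self, counts, data):
        g = data.draw(st.integers(1, sum(counts)))
        assert rarefied_richness(counts, g) == pytest.approx(
            exhaustive_rarefaction(counts, g), abs=1e-9
        )

    def test_invalid_g_rejected(self):
        with pytest.raises(ValueError):
            rarefied_richness([3, 2], 0)
        with pytest.raises(ValueError):
            rarefied_richness([3, 2], 6)

    def test_haplotype_richness_full_sample_is_observed_count(self):
        counts = [3, 1, 1]
        assert haplotype_richness(counts, 5) == pytest.approx(3.0)
        assert haplotype_richness([7], 3) == pytest.approx(1.0)
        assert haplotype_richness([3, 1, 1], 3) == pytest.approx(
            exhaustive_rarefaction([3, 1, 1], 3), abs=1e-12
        )


class TestDiversity:
    def test_expected_heterozygosity_closed_forms(self):
        fixed = table_from_pairs([(1, 1)] * 5)
        assert expected_heterozygosity(allele_counts(fixed)).iloc[0, 0] == 0.0
        # p = 0.5 with n = 5 diploids: (10/9) * 0.5
        t = table_from_pairs([(1, 1), (1, 1), (2, 2), (2, 2), (1, 2)])
        val = expected_heterozygosity(allele_counts(t)).iloc[0, 0]
        assert val == pytest.approx(10 / 9 * 0.5, abs=1e-12)

    def test_heterozygosity_undefined_below_two_individuals(self):
        t = table_from_pairs([(1, 2)])
        assert np.isnan(expected_heterozygosity(allele_counts(t)).iloc[0, 0])

    def test_haplotype_diversity_closed_forms(self):
        assert haplotype_diversity([5]) == 0.0
        assert haplotype_diversity([1, 1]) == pytest.approx(1.0)
        assert haplotype_diversity([3, 1]) == pytest.approx(0.5, abs=1e-12)

    def test_nucleotide_diversity_pairwise(self):
        same = HaplotypeAlignment(["a", "b"], ["P"] * 2, ["ACGT" * 10] * 2)
        assert nucleotide_diversity(same) == 0.0
        s1 = "A" * 465
        s2 = "A" * 464 + "C"
        two = HaplotypeAlignment(["a", "b"], ["P"] * 2, [s1, s2])
        assert nucleotide_diversity(two) == pytest.approx(1 / 465)

    def test_nucleotide_diversity_order_invariant(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(6)]
        fwd = HaplotypeAlignment([f"s{i}" for i in range(6)], ["P"] * 6, seqs)
        rev = HaplotypeAlignment(
            [f"s{i}" for i in range(6)], ["P"] * 6, seqs[::-1]
        )
        assert nucleotide_diversity(fwd) == pytest.approx(
            nucleotide_diversity(rev)
        )


class TestPermutationTest:
    def test_p_value_lower_bound_and_null_behaviour(self):
        counts = {"L1": np.array([10, 10, 10])}
        res = permutation_differentiation_test(counts, dict(counts), 199, seed=0)
        assert res.per_locus_p["L1"] >= 1 / 200
        assert res.per_locus_p["L1"] > 0.5  # identical content

    def test_disjoint_fixed_alleles_reach_the_minimum(self):
        a = {"L1": np.array([40, 0])}
        b = {"L1": np.array([0, 40])}
        res = permutation_differentiation_test(a, b, 199, seed=1)
        assert res.per_locus_p["L1"] == pytest.approx(1 / 200)
        assert res.combined_p < 0.01

    def test_zero_copy_sample_rejected(self):
        with pytest.raises(ValueError):
            permutation_differentiation_test(
                {"L1": np.array([5, 5])}, {"L1": np.array([0, 0])}, 199, 0
            )

    def test_n_perm_floor(self):
        with pytest.raises(ValueError):
            permutation_differentiation_test(
                {"L1": np.array([5, 5])}, {"L1": np.array([5, 5])}, 10, 0
            )

    def test_table_wrapper_runs_multi_locus(self):
        rng = np.random.default_rng(2)
        geno = rng.integers(1, 4, size=(40, 3, 2))
        t = GenotypeTable(
            [f"i{k}" for k in range(40)],
            ["A"] * 20 + ["B"] * 20,
            ["L1", "L2", "L3"],
            geno,
        )
        res = differentiation_test_from_table(t, "A", "B", n_perm=199, seed=0)
        assert set(res.per_locus_p.index) == {"L1", "L2", "L3"}
        assert 0 < res.combined_p <= 1


class TestEBFst:
    def test_identical_large_samples_shrink_to_zero(self):
        c = {"L1": np.array([5000, 5000, 2500]), "L2": np.array([4000, 6000])}
        r = eb_fst_pair(c, {k: v.copy() for k, v in c.items()})
        assert r.fst < 1e-3

    def test_symmetry_and_relabel_invariance(self):
        a = {"L1": np.array([30, 50, 20]), "L2": np.array([10, 90])}
        b = {"L1": np.array([50, 30, 20]), "L2": np.array([40, 60])}
        r_ab = eb_fst_pair(a, b)
        r_ba = eb_fst_pair(b, a)
        assert r_ab.fst == pytest.approx(r_ba.fst, rel=1e-9)
        perm = [2, 0, 1]
        a2 = {"L1": a["L1"][perm], "L2": a["L2"]}
        b2 = {"L1": b["L1"][perm], "L2": b["L2"]}
        assert eb_fst_pair(a2, b2).fst == pytest.approx(r_ab.fst, rel=1e-9)

    def test_monotone_in_frequency_divergence(self):
        prev = -1.0
        for k in [50, 40, 30, 20, 10, 0]:
            a = {"L1": np.array([100 - k, k], dtype=float)}
            b = {"L1": np.array([k, 100 - k], dtype=float)}
            fst = eb_fst_pair(a, b).fst
            assert fst >= prev - 1e-12
            prev = fst

    def test_marginal_likelihood_matches_scipy(self):
        x = np.array([12.0, 5.0, 3.0])
        pbar = np.array([0.5, 0.3, 0.2])
        theta = 7.3
        ours = _dm_loglik(theta, [x], [pbar])
        ref = dirichlet_multinomial.logpmf(x, theta * pbar, int(x.sum()))
        # our likelihood omits the multinomial coefficient (constant in theta)
        from scipy.special import gammaln

        coeff = gammaln(x.sum() + 1) - gammaln(x + 1).sum()
        assert ours + coeff == pytest.approx(float(ref), abs=1e-10)


class TestUPGMA:
    def test_three_taxon_hand_agglomeration(self):
        from seabream.io import tree_to_newick

        d, expected = hand_upgma_3taxa()
        tree = upgma(DistanceMatrix(["A", "B", "C"], d))
        assert tree_to_newick(tree) == expected

    def test_ultrametric_for_random_matrices(self):
        rng = np.random.default_rng(3)
        for n in [3, 5, 8]:
            m = rng.uniform(0.2, 2.0, (n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            tree = upgma(DistanceMatrix([f"x{i}" for i in range(n)], m))
            assert tree.is_ultrametric()

    def test_matches_scipy_average_linkage_heights(self):
        rng = np.random.default_rng(4)
        n = 7
        m = rng.uniform(0.2, 2.0, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = [f"x{i}" for i in range(n)]
        tree = upgma(DistanceMatrix(labels, m))
        # cophenetic distances from scipy's independent implementation
        coph = squareform(cophenet(linkage(squareform(m), method="average")))
        depths = tree.leaf_depths()

        def pair_height(a, b):
            # merge height of a,b = half their cophenetic distance
            return coph[labels.index(a), labels.index(b)] / 2

        # every leaf depth equals the root height; compare pairwise merge
        # distances instead
        for i in range(n):
            for j in range(i + 1, n):
                node = tree.root
                # walk down to the last common ancestor
                while True:
                    child = next(
                        (
                            c
                            for c in node.children
                            if {labels[i], labels[j]} <= set(c.leaves())
                        ),
                        None,
                    )
                    if child is None:
                        break
                    node = child
                assert node.height == pytest.approx(
                    pair_height(labels[i], labels[j])
                )

    def test_nan_rejected(self):
        m = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], m)

    def test_deterministic_tie_break(self):
        # four equidistant leaves: ties resolve toward the lexicographically
        # smallest member tuple, so the topology is fully determined no
        # matter the input label order
        from seabream.io import tree_to_newick

        m = np.full((4, 4), 1.0)
        np.fill_diagonal(m, 0.0)
        expected = "(((A:0.5,B:0.5):0,C:0.5):0,D:0.5);"
        for order in [["D", "C", "B", "A"], ["A", "B", "C", "D"],
                      ["B", "D", "A", "C"]]:
            tree = upgma(DistanceMatrix(order, m))
            assert tree_to_newick(tree) == expected


def test_allelic_richness_report_shape():
    rng = np.random.default_rng(9)
    geno = rng.integers(1, 5, size=(30, 2, 2))
    t = GenotypeTable(
        [f"i{k}" for k in range(30)], ["A"] * 15 + ["B"] * 15, ["L1", "L2"], geno
    )
    ft = allele_counts(t)
    rich = allelic_richness(ft, g=10)
    assert rich.shape == (2, 2)
    assert (rich.to_numpy() >= 1).all()
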