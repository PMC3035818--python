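"""Differentiation estimators against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from introscan.exceptions import ParameterError, SampleSizeError, StatisticError
from introscan.genotypes import GenotypeTable, Individual, Locus
from introscan.popstats import (
    bootstrap_support,
    dps_distance_matrix,
    drop_inbred_alleles,
    expected_heterozygosity,
    fst_wc,
    fst_wc_multilocus,
    gst,
    gst_prime,
    inbred_drop_mean,
    nj_tree,
    per_locus_stats,
    rarefied_allelic_richness,
    tree_bipartitions,
)


def wc_theta_oracle(counts):
    """Haploid Weir-Cockerham theta via explicit per-deme, per-allele
    loops (independent coding path from the vectorized implementation)."""
    r = len(counts)
    n = [sum(row) for row in counts]
    n_tot = sum(n)
    alleles = range(len(counts[0]))
    n_c = (n_tot - sum(ni**2 for ni in n) / n_tot) / (r - 1)
    num = den = 0.0
    for a in alleles:
        pbar = sum(counts[i][a] for i in range(r)) / n_tot
        msp = sum(
            n[i] * (counts[i][a] / n[i] - pbar) ** 2 for i in range(r)
        ) / (r - 1)
        msg = sum(
            n[i] * (counts[i][a] / n[i]) * (1 - counts[i][a] / n[i])
            for i in range(r)
        ) / (n_tot - r)
        num += msp - msg
        den += msp + (n_c - 1) * msg
    return num / den


class TestExpectedHeterozygosity:
    @pytest.mark.parametrize(
        "freqs,expect",
        [([1.0], 0.0), ([0.5, 0.5], 0.5), ([0.25] * 4, 0.75)],
    )
    def test_known_values(self, freqs, expect):
        assert expected_heterozygosity(freqs) == pytest.approx(expect)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ParameterError):
            expected_heterozygosity([1.2, -0.2])


class TestFstWC:
    def test_complete_fixation(self):
        assert fst_wc([[4, 0], [0, 4]]) == pytest.approx(1.0)

    def test_no_differentiation_large_equal_samples(self):
        assert abs(fst_wc([[100, 100], [100, 100]])) < 0.02

    def test_monomorphic_undefined(self):
        assert math.isnan(fst_wc([[5, 0], [5, 0]]))

    def test_matches_oracle_on_small_instances(self):
        cases = [
            [[3, 1], [1, 3]],
            [[2, 2, 0], [0, 2, 2]],
            [[5, 1], [2, 4]],
            [[1, 1, 1, 1], [4, 0, 0, 0]],
            [[7, 3], [3, 7]],
        ]
        for counts in cases:
            assert fst_wc(counts) == pytest.approx(
                wc_theta_oracle(counts), abs=1e-12
            )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_oracle_on_random_instances(self, seed):
        r = np.random.default_rng(seed)
        a = int(r.integers(2, 5))
        counts = r.integers(0, 6, size=(2, a))
        counts[:, 0] += 2  # ensure >= 2 copies per deme
        if (counts.sum(axis=0) > 0).sum() < 2:
            return
        assert fst_wc(counts) == pytest.approx(
            wc_theta_oracle(counts.tolist()), abs=1e-12
        )

    def test_relabelling_invariance(self):
        counts = [[3, 5, 2], [6, 1, 3]]
        perm = [[5, 2, 3], [1, 3, 6]]
        assert fst_wc(counts) == pytest.approx(fst_wc(perm), abs=1e-12)

    def test_multilocus_pools_components(self):
        l1, l2 = [[3, 1], [1, 3]], [[5, 1], [2, 4]]
        combined = fst_wc_multilocus([l1, l2])
        assert min(fst_wc(l1), fst_wc(l2)) <= combined <= max(
            fst_wc(l1), fst_wc(l2)
        )

    def test_deme_needs_two_copies(self):
        with pytest.raises(SampleSizeError):
            fst_wc([[1, 0], [3, 3]])


class TestGstPrime:
    def test_fixed_demes_reach_one(self):
        g, hs, _ = gst([[4, 0], [0, 4]])
        assert (g, hs) == (1.0, 0.0)
        assert gst_prime([[4, 0], [0, 4]]) == pytest.approx(1.0)

    def test_equal_frequencies_give_zero(self):
        assert gst_prime([[5, 5], [5, 5]]) == pytest.approx(0.0)

    def test_prime_at_least_gst_and_at_most_one(self):
        r = np.random.default_rng(3)
        for _ in range(50):
            counts = r.integers(1, 9, size=(2, int(r.integers(2, 5))))
            g, _, _ = gst(counts)
            gp = gst_prime(counts)
            assert gp >= g - 1e-12
            assert gp <= 1.0 + 1e-12

    def test_monomorphic_undefined(self):
        assert math.isnan(gst_prime([[5, 0], [5, 0]]))

    def test_hedrick_worked_form(self):
        # hand evaluation of G'ST = G (k-1+HS) / ((k-1)(1-HS)) with k=2
        counts = [[6, 2], [2, 6]]
        g, hs, ht = gst(counts)
        assert gst_prime(counts) == pytest.approx(g * (1 + hs) / (1 - hs))


class TestRarefaction:
    def test_full_sample_returns_observed_count(self):
        assert rarefied_allelic_richness([5, 3, 2], 10) == pytest.approx(3.0)

    def test_single_copy(self):
        assert rarefied_allelic_richness([5, 3, 2], 1) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """E[A_5] for counts (5,3,2) equals the average distinct-allele
        count over all C(10,5) subsamples."""
        pool = [0] * 5 + [1] * 3 + [2] * 2
        vals = [
            len(set(sub)) for sub in itertools.combinations(pool, 5)
        ]
        assert rarefied_allelic_richness([5, 3, 2], 5) == pytest.approx(
            np.mean(vals), abs=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_nondecreasing_in_g(self, seed):
        r = np.random.default_rng(seed)
        counts = r.integers(1, 8, size=int(r.integers(2, 6)))
        n = int(counts.sum())
        vals = [rarefied_allelic_richness(counts, g) for g in range(1, n + 1)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_g_beyond_total_rejected(self):
        with pytest.raises(ParameterError):
            rarefied_allelic_richness([2, 2], 5)


def _table(genotypes, inbred_ids=(), species=None, collections=None,
           chroms=None):
    n_ind = len(genotypes)
    n_loc = len(genotypes[0])
    species = species or ["A"] * n_ind
    collections = collections or ["c"] * n_ind
    inds = [
        Individual(
            id=f"i{k}",
            species=species[k],
            collection=collections[k],
            inbred=f"i{k}" in inbred_ids,
        )
        for k in range(n_ind)
    ]
    chroms = chroms or ["X"] * n_loc
    loci = [Locus(name=f"L{j}", chromosome=chroms[j]) for j in range(n_loc)]
    return GenotypeTable(individuals=inds, loci=loci, genotypes=genotypes)


class TestInbredDrop:
    def test_all_homozygous_is_a_fixed_point(self, rng):
        tab = _table([[(1, 1)], [(2, 2)], [(1, 1)]], inbred_ids={"i0", "i1"})
        single = inbred_drop_mean(tab, "mean_he", replicates=1, rng=rng)
        many = inbred_drop_mean(tab, "mean_he", replicates=20, rng=rng)
        assert single == pytest.approx(many)

    def test_fixed_seed_reproducible(self):
        tab = _table([[(1, 2)], [(2, 2)]], inbred_ids={"i0"})
        a = inbred_drop_mean(tab, "mean_he", 5, np.random.default_rng(9))
        b = inbred_drop_mean(tab, "mean_he", 5, np.random.default_rng(9))
        assert a == b

    def test_heterozygote_drop_matches_two_outcome_average(self, rng):
        """One inbred A/B heterozygote among homozygotes: the drop mean
        must sit within 3 SE of the exact average over both outcomes."""
        genos = [[(1, 2)], [(1, 1)], [(1, 1)], [(2, 2)]]
        tab = _table(genos, inbred_ids={"i0"})

        def he_outcome(kept):
            counts = {1: 4, 2: 2}
            counts[kept] += 1
            tot = sum(counts.values())
            return 1 - sum((c / tot) ** 2 for c in counts.values())

        exact = 0.5 * (he_outcome(1) + he_outcome(2))
        reps = 200
        draws = [
            inbred_drop_mean(tab, "mean_he", 1, rng) for _ in range(reps)
        ]
        se = np.std(draws, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(draws) - exact) <= 3 * se

    def test_non_inbred_untouched(self, rng):
        tab = _table([[(1, 2)], [(3, 4)]], inbred_ids=set())
        dropped = drop_inbred_alleles(tab, rng)
        assert dropped.genotypes == tab.genotypes


class TestDps:
    def test_identical_profiles_distance_zero(self):
        genos = [[(1, 2)], [(1, 2)], [(1, 2)], [(1, 2)]]
        tab = _table(genos, collections=["g1", "g1", "g2", "g2"])
        _, d = dps_distance_matrix(tab, lambda ind: ind.collection)
        assert d[0, 1] == pytest.approx(0.0)

    def test_disjoint_alleles_distance_one(self):
        genos = [[(1, 1)], [(2, 2)]]
        tab = _table(genos, collections=["g1", "g2"])
        _, d = dps_distance_matrix(tab, lambda ind: ind.collection)
        assert d[0, 1] == pytest.approx(1.0)

    def test_half_shared_worked_example(self):
        # g1 = {A:0.5, B:0.5}, g2 = {A:1.0} -> D = 0.5
        genos = [[(1, 2)], [(1, 1)]]
        tab = _table(genos, collections=["g1", "g2"])
        _, d = dps_distance_matrix(tab, lambda ind: ind.collection)
        assert d[0, 1] == pytest.approx(0.5)

    def test_grouping_by_mapping(self):
        genos = [[(1, 1)], [(2, 2)]]
        tab = _table(genos)
        _, d = dps_distance_matrix(tab, {"i0": "x", "i1": "y"})
        assert d[0, 1] == pytest.approx(1.0)

    def test_single_group_rejected(self):
        tab = _table([[(1, 1)], [(1, 1)]])
        with pytest.raises(ParameterError):
            dps_distance_matrix(tab, lambda ind: "same")


class TestNeighbourJoining:
    def test_additive_four_taxon_distances_recover_topology(self):
        # tree ((a:1,b:2):1,(c:3,d:1)); additive distances
        d = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(d, ["a", "b", "c", "d"])
        parts = tree_bipartitions(tree)
        expect = frozenset(
            (frozenset({"a", "b"}), frozenset({"c", "d"}))
        )
        assert parts == {expect}

    def test_three_taxa_branch_lengths_solve_three_point_formulas(self):
        d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
        tree = nj_tree(d, ["a", "b", "c"])
        tips = {t.name: t.length for t in tree.tips()}
        assert tips["a"] == pytest.approx((5 + 9 - 8) / 2)
        assert tips["b"] == pytest.approx((5 + 8 - 9) / 2)
        assert tips["c"] == pytest.approx((9 + 8 - 5) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(SampleSizeError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_bootstrap_on_constant_loci_gives_full_support(self, rng):
        # four groups, 5 identical informative loci: every bipartition of
        # the point tree must appear in all bootstrap replicates
        genos = [
            [(1, 1)] * 5,
            [(1, 2)] * 5,
            [(5, 5)] * 5,
            [(5, 6)] * 5,
        ]
        tab = _table(genos, collections=["g1", "g2", "g3", "g4"])
        tree, support = bootstrap_support(
            tab, lambda ind: ind.collection, replicates=25, rng=rng
        )
        assert support  # at least one internal bipartition
        assert all(v == 100.0 for v in support.values())


class TestPerLocusStats:
    def test_fixed_shared_locus_flagged_nan(self):
        genos = [[(1, 2), (7, 7)], [(1, 1), (7, 7)]]
        tab = _table(
            genos, species=["A", "B"], chroms=["X", "4"]
        )
        stats = per_locus_stats(tab)
        assert math.isnan(stats[1].fst) and math.isnan(stats[1].gst_prime)
        assert stats[1].allele_count == 1
        assert not math.isnan(stats[0].fst)
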