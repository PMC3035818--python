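"""Alignment container and diversity statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from introscan.alignment import (
    between_species_summary,
    diversity_summary,
    jukes_cantor,
    read_alignment,
    silent_site_mask,
)
from introscan.exceptions import (
    AlignmentError,
    FrameError,
    JCDomainError,
    MetadataError,
    SampleSizeError,
)
from conftest import make_alignment


class TestReadAlignment:
    def test_gap_free_alignment_analyses_all_columns(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">s1\nACGT\n>s2\nACGA\n>s3\nACGT\n>s4\nACGA\n")
        labels = {f"s{i}": {"species": "A", "collection": "x"} for i in range(1, 5)}
        aln = read_alignment(fa, labels)
        assert aln.analysed_sites == aln.length == 4

    def test_gap_column_excluded_but_recorded(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">s1\nAC-T\n>s2\nACGA\n")
        labels = {"s1": {"species": "A"}, "s2": {"species": "A"}}
        aln = read_alignment(fa, labels)
        assert aln.analysed_sites == 3
        assert list(aln.excluded_columns()) == [2]

    def test_missing_metadata_is_an_error(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">s1\nACGT\n>s2\nACGT\n")
        with pytest.raises(MetadataError):
            read_alignment(fa, {"s1": {"species": "A"}})

    def test_unequal_lengths_rejected(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">s1\nACGT\n>s2\nACG\n")
        labels = {"s1": {"species": "A"}, "s2": {"species": "A"}}
        with pytest.raises(AlignmentError):
            read_alignment(fa, labels)


class TestDiversitySummary:
    def test_monomorphic_sample(self):
        aln = make_alignment({f"s{i}": "ACGTACGT" for i in range(4)})
        d = diversity_summary(aln)
        assert (d.S, d.h, d.Hd, d.pi_jc) == (0, 1, 0.0, 0.0)

    def test_two_haplotypes_at_equal_counts(self):
        # n=4 with counts (2,2): Hd = (4/3)(1 - 0.5) = 0.6667 -> printed 0.67
        aln = make_alignment(
            {"a": "AAAA", "b": "AAAA", "c": "AAAT", "d": "AAAT"}
        )
        d = diversity_summary(aln)
        assert d.h == 2
        assert d.Hd == pytest.approx(2 / 3, abs=1e-12)
        assert f"{d.Hd:.2f}" == "0.67"

    def test_jc_correction_on_small_distance(self):
        # 2 sequences of 100 sites differing at 1 site
        base = "A" * 100
        aln = make_alignment({"a": base, "b": "T" + base[1:]})
        d = diversity_summary(aln)
        assert d.pi_raw == pytest.approx(0.01)
        assert d.pi_jc == pytest.approx(0.010067, abs=1e-6)

    def test_sample_size_error(self):
        with pytest.raises(SampleSizeError):
            diversity_summary(make_alignment({"a": "ACGT"}))

    def test_jc_domain_error(self):
        with pytest.raises(JCDomainError):
            jukes_cantor(0.8)

    def test_pi_matches_bruteforce_pair_mean(self, rng):
        """pi_raw equals the average p-distance over all C(n,2) pairs."""
        for _ in range(20):
            n, L = int(rng.integers(2, 7)), int(rng.integers(5, 30))
            base = rng.choice(list("ACGT"), L)
            seqs = {}
            for i in range(n):
                seq = base.copy()
                for j in rng.choice(L, size=min(3, L), replace=False):
                    seq[j] = rng.choice(list("ACGT"))
                seqs[f"s{i}"] = "".join(seq)
            aln = make_alignment(seqs)
            pairs = list(itertools.combinations(seqs.values(), 2))
            expect = np.mean(
                [sum(x != y for x, y in zip(a, b)) / L for a, b in pairs]
            )
            assert diversity_summary(aln).pi_raw == pytest.approx(expect)

    def test_hd_relabelling_invariance_and_uniform_maximum(self):
        """Hd depends only on the haplotype count spectrum and is maximal
        for uniform frequencies (all compositions, n <= 8)."""

        def hd(counts):
            n = sum(counts)
            p = np.array(counts) / n
            return n * (1 - np.sum(p**2)) / (n - 1)

        for n in range(2, 9):
            for h in range(1, n + 1):
                if n % h:
                    continue
                best = hd([n // h] * h)
                for comp in _compositions(n, h):
                    assert hd(comp) <= best + 1e-12
                    assert hd(comp) == pytest.approx(hd(sorted(comp)))

    def test_duplicating_all_sequences_rescales_pi_exactly(self, toy_alignment):
        """Doubling every sequence adds zero-distance duplicate pairs:
        pi' = pi * 2(n-1)/(2n-1) for the C(n,2)-pair mean."""
        n = toy_alignment.n
        doubled = make_alignment(
            {
                **{r.id: r.residues for r in toy_alignment.records},
                **{r.id + "_dup": r.residues for r in toy_alignment.records},
            }
        )
        pi = diversity_summary(toy_alignment).pi_raw
        pi2 = diversity_summary(doubled).pi_raw
        assert pi2 == pytest.approx(pi * 2 * (n - 1) / (2 * n - 1))


def _compositions(n, k):
    if k == 1:
        yield (n,)
        return
    for first in range(1, n - k + 2):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


class TestBetweenSpecies:
    def test_single_fixed_difference(self):
        aln = make_alignment(
            {"a1": "AAAA", "a2": "AAAA", "b1": "AAAT", "b2": "AAAT"},
            species={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        res = between_species_summary(aln, "A", "B")
        assert (res.F, res.S_star) == (1, 0)

    def test_shared_polymorphism(self):
        aln = make_alignment(
            {"a1": "AC", "a2": "AT", "b1": "AC", "b2": "AT"},
            species={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        res = between_species_summary(aln, "A", "B")
        assert (res.F, res.S_star) == (0, 1)

    def test_ks_is_jc_corrected_pair_mean(self):
        aln = make_alignment(
            {"a": "AAAA", "b": "AAGG"}, species={"a": "A", "b": "B"}
        )
        res = between_species_summary(aln, "A", "B")
        assert res.Ks == pytest.approx(-0.75 * math.log(1 - 2 / 3), abs=1e-4)

    def test_empty_species_sample(self, toy_alignment):
        with pytest.raises(SampleSizeError):
            between_species_summary(toy_alignment, "spA", "missing")

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_fixed_plus_shared_bounded_by_segregating(self, seed):
        """F + S* <= total segregating sites for any two-species split."""
        r = np.random.default_rng(seed)
        n, L = int(r.integers(4, 8)), int(r.integers(4, 16))
        base = r.choice(list("ACGT"), L)
        seqs = {}
        for i in range(n):
            seq = base.copy()
            for j in r.choice(L, size=min(2, L), replace=False):
                seq[j] = r.choice(list("ACGT"))
            seqs[f"s{i}"] = "".join(seq)
        species = {f"s{i}": ("A" if i < n // 2 else "B") for i in range(n)}
        aln = make_alignment(seqs, species=species)
        res = between_species_summary(aln, "A", "B")
        s_total = diversity_summary(aln).S
        assert res.F + res.S_star <= s_total


class TestSilentSiteMask:
    def test_fourfold_glycine_column_included(self):
        # GGN codons: third position is 4-fold degenerate
        aln = make_alignment({"a": "GGAGGC", "b": "GGTGGG"})
        mask = silent_site_mask(aln)
        assert {2, 5} <= mask

    def test_first_codon_position_excluded(self):
        aln = make_alignment({"a": "ATGGGA", "b": "ATGGGC"})
        mask = silent_site_mask(aln)
        assert 0 not in mask and 2 not in mask  # ATG: nondegenerate

    def test_offset_beyond_length_is_frame_error(self, toy_alignment):
        with pytest.raises(FrameError):
            silent_site_mask(toy_alignment, frame_offset=toy_alignment.length)

    def test_internal_stop_in_all_sequences(self):
        aln = make_alignment({"a": "TAAGGA", "b": "TAGGGA"})
        with pytest.raises(FrameError):
            silent_site_mask(aln)
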