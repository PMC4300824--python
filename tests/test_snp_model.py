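"""The binomial error model, dynamic masking and site calling."""

from __future__ import annotations

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import homeoseq as hs
from homeoseq.snp_model import call_organism_columns


def binom_tail(k: int, n: int, p: float) -> float:
    """Independent brute-force oracle: sum of pmf terms from k to n."""
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


PARAMS = hs.SnpModelParams()  # epsilon 0.03 -> per-base error 0.01, alpha 1e-3


class TestAllelePvalue:
    def test_zero_count_is_certain(self):
        assert hs.allele_pvalue(0, 50, PARAMS) == 1.0

    def test_matches_bruteforce_example(self):
        # two of ten reads showing the same wrong base
        assert hs.allele_pvalue(2, 10, PARAMS) == pytest.approx(
            0.004266200242831419, rel=1e-12
        )

    def test_unanimous_closed_form(self):
        # all three reads agree: (epsilon/3)^3
        assert hs.allele_pvalue(3, 3, PARAMS) == pytest.approx(1e-6, rel=1e-9)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            hs.allele_pvalue(5, 3, PARAMS)

    @given(n=st.integers(1, 40), k=st.integers(1, 40))
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_non_increasing_in_k(self, n, k):
        if k > n:
            k = n
        if k > 1:
            assert hs.allele_pvalue(k, n, PARAMS) <= hs.allele_pvalue(k - 1, n, PARAMS)


class TestMinConfidentCoverage:
    def test_default_parameters_need_two_reads(self):
        assert hs.min_confident_coverage(PARAMS) == 2

    def test_lenient_alpha_needs_one(self):
        assert hs.min_confident_coverage(hs.SnpModelParams(0.03, 0.05)) == 1

    def test_tiny_error_rate_needs_one(self):
        assert hs.min_confident_coverage(hs.SnpModelParams(1e-9, 1e-3)) == 1

    @pytest.mark.parametrize("epsilon", [0.003, 0.03, 0.15])
    @pytest.mark.parametrize("alpha", [0.05, 1e-3, 1e-6])
    def test_defining_inequality(self, epsilon, alpha):
        params = hs.SnpModelParams(epsilon, alpha)
        n = hs.min_confident_coverage(params)
        p = params.per_base_error
        assert p**n < alpha
        if n > 1:
            assert p ** (n - 1) >= alpha

    def test_monotone_in_alpha_and_epsilon(self):
        alphas = [0.1, 1e-2, 1e-3, 1e-4]
        ns = [hs.min_confident_coverage(hs.SnpModelParams(0.03, a)) for a in alphas]
        assert ns == sorted(ns)  # non-increasing alpha -> non-decreasing N_min
        epss = [0.003, 0.01, 0.03, 0.1]
        ns = [hs.min_confident_coverage(hs.SnpModelParams(e, 1e-3)) for e in epss]
        assert ns == sorted(ns)


class TestOrganismCall:
    def test_clear_haploid_call(self):
        alleles, masked = hs.call_organism_site({"A": 20}, 1, PARAMS)
        assert alleles == {"A"} and not masked

    def test_low_coverage_masked(self):
        alleles, masked = hs.call_organism_site({"A": 1}, 1, PARAMS)
        assert masked and alleles == frozenset()

    def test_ploidy_caps_alleles(self):
        counts = {"A": 10, "G": 12}
        dip, _ = hs.call_organism_site(counts, 2, PARAMS)
        hap, _ = hs.call_organism_site(counts, 1, PARAMS)
        assert dip == {"A", "G"}
        assert hap == {"G"}  # most frequent wins under the haploid cap

    def test_tie_broken_by_base_order(self):
        alleles, _ = hs.call_organism_site({"G": 8, "A": 8}, 1, PARAMS)
        assert alleles == {"A"}

    def test_error_noise_not_called(self):
        # one stray read against deep coverage is consistent with error
        alleles, masked = hs.call_organism_site({"A": 99, "G": 1}, 2, PARAMS)
        assert alleles == {"A"} and not masked

    def test_adding_allele_observations_never_masks(self):
        # supporting evidence accumulates: k and n grow together
        for k in range(2, 30):
            _, masked = hs.call_organism_site({"A": k}, 1, PARAMS)
            assert not masked

    @given(
        counts=st.lists(st.integers(0, 60), min_size=4, max_size=4),
        ploidy=st.integers(1, 2),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_vectorised_matches_scalar(self, counts, ploidy):
        arr = np.array([counts], dtype=np.int64)
        allele_v, masked_v = call_organism_columns(arr, ploidy, PARAMS)
        alleles_s, masked_s = hs.call_organism_site(
            dict(zip("ACGT", counts)), ploidy, PARAMS
        )
        assert {"ACGT"[i] for i in np.nonzero(allele_v[0])[0]} == alleles_s
        assert bool(masked_v[0]) == masked_s

    @given(
        counts=st.lists(st.integers(0, 40), min_size=4, max_size=4),
        ploidy=st.integers(1, 2),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_allele_set_respects_significance_and_cap(self, counts, ploidy):
        alleles, masked = hs.call_organism_site(dict(zip("ACGT", counts)), ploidy, PARAMS)
        n = sum(counts)
        assert len(alleles) <= ploidy
        for base in alleles:
            k = counts["ACGT".index(base)]
            assert binom_tail(k, n, PARAMS.per_base_error) < PARAMS.alpha
        if masked:
            assert alleles == frozenset()


class TestSiteCall:
    def test_diagnostic_site(self, two_parent_protocol):
        site = hs.call_site(
            {"parent1": {"A": 20}, "parent2": {"G": 15}, "child": {"A": 10, "G": 12}},
            two_parent_protocol, PARAMS,
        )
        assert site.diagnostic_alleles == {"A": 1, "G": 2}
        assert site.novel_alleles == frozenset()

    def test_shared_allele_not_diagnostic(self, two_parent_protocol):
        site = hs.call_site(
            {"parent1": {"A": 20}, "parent2": {"A": 18}, "child": {"A": 30}},
            two_parent_protocol, PARAMS,
        )
        assert site.diagnostic_alleles == {}

    def test_masked_parent_blocks_diagnosis(self, two_parent_protocol):
        site = hs.call_site(
            {"parent1": {}, "parent2": {"G": 15}, "child": {"G": 20}},
            two_parent_protocol, PARAMS,
        )
        assert site.organisms["parent1"].masked
        assert site.diagnostic_alleles == {}

    def test_novel_allele_in_child(self, two_parent_protocol):
        site = hs.call_site(
            {"parent1": {"A": 20}, "parent2": {"A": 18}, "child": {"A": 30, "T": 9}},
            two_parent_protocol, PARAMS,
        )
        # P(X >= 9 | n=39, p=0.01) ~ 1.6e-10: T is real, and no parent has it
        assert site.novel_alleles == {"T"}

    def test_parent_label_permutation_symmetry(self, two_parent_protocol):
        counts = {"parent1": {"A": 20}, "parent2": {"G": 15}, "child": {"A": 9, "G": 11}}
        swapped = {"parent1": counts["parent2"], "parent2": counts["parent1"],
                   "child": counts["child"]}
        site = hs.call_site(counts, two_parent_protocol, PARAMS)
        site_sw = hs.call_site(swapped, two_parent_protocol, PARAMS)
        assert site_sw.diagnostic_alleles == {
            b: {1: 2, 2: 1}[k] for b, k in site.diagnostic_alleles.items()
        }
        assert site_sw.novel_alleles == site.novel_alleles


class TestDiagnosticSites:
    def test_no_polymorphism_no_sites(self, two_parent_protocol):
        sites = [
            hs.call_site(
                {"parent1": {"A": 20}, "parent2": {"A": 20}, "child": {"A": 40}},
                two_parent_protocol, PARAMS, position=i,
            )
            for i in range(5)
        ]
        assert hs.diagnostic_sites(sites) == []

    def test_planted_substitutions_recovered_exactly(self, tmp_path):
        # deep even coverage, no sequencing error: calls must equal the truth
        params = hs.SimParams(
            seed=5, n_genes=5, gene_length=(400, 600), coverage=30, error_rate=0.0
        )
        system = hs.simulate_system(params, tmp_path / "sim")
        protocol = hs.parse_protocol(system.protocol_path)
        reference = hs.read_reference(system.reference_path)
        reads = {g.gene_id: [] for g in reference}
        for s in protocol.samples:
            for r in hs.read_alignments(s.path, reference, s):
                reads[r.gene_id].append(r)
        for gene in reference:
            pile = hs.build_pileup(reads[gene.gene_id], gene, protocol)
            calls = hs.call_gene_sites(pile, protocol, PARAMS)
            got = hs.diagnostic_sites(calls)
            expected = system.truth.diagnostic_positions(gene.gene_id)
            # positions with zero coverage at gene edges stay masked
            informative = [p for p in expected if calls.informative[p]]
            assert got == informative
            assert set(informative) >= set(got)

    def test_identical_parents_yield_none(self, tmp_path):
        params = hs.SimParams(seed=6, n_genes=3, divergence=0.0, coverage=30)
        system = hs.simulate_system(params, tmp_path / "sim")
        protocol = hs.parse_protocol(system.protocol_path)
        reference = hs.read_reference(system.reference_path)
        reads = {g.gene_id: [] for g in reference}
        for s in protocol.samples:
            for r in hs.read_alignments(s.path, reference, s):
                reads[r.gene_id].append(r)
        for gene in reference:
            pile = hs.build_pileup(reads[gene.gene_id], gene, protocol)
            calls = hs.call_gene_sites(pile, protocol, PARAMS)
            assert hs.diagnostic_sites(calls) == []
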