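"""Read classification into parent / multi-parent / unknown, and tallies."""

from __future__ import annotations

import numpy as np
import pytest

import homeoseq as hs
from homeoseq.read_classify import ClassifyError, CATEGORY_MULTI, CATEGORY_UNKNOWN
from homeoseq.snp_model import GeneSiteCalls

from test_pileup import make_read


def make_calls(
    length: int,
    diag: dict[int, dict[str, int]] | None = None,
    novel: dict[int, str] | None = None,
    masked_positions: set[int] = frozenset(),
    gene_id: str = "g",
    n_parents: int = 2,
) -> GeneSiteCalls:
    """Build site calls from deep synthetic pileups matching a description.

    Diagnostic sites get disjoint parental alleles; every other position is a
    monomorphic 'A' shared by all organisms; ``masked_positions`` get zero
    parent coverage.  Novel child alleles ride on top of shared sites.
    """
    diag = diag or {}
    novel = novel or {}
    samples = tuple(
        [hs.SampleSpec(f"P{k}", f"parent{k}", "mRNA", 1, "x", "sam")
         for k in range(1, n_parents + 1)]
        + [hs.SampleSpec("C", "child", "mRNA", 1, "x", "sam")]
    )
    protocol = hs.ProtocolTable(samples, {k: 1 for k in range(1, n_parents + 1)})
    pile = hs.GenePileup(gene_id=gene_id, length=length)
    base_i = {b: i for i, b in enumerate("ACGT")}
    for k in range(1, n_parents + 1):
        arr = np.zeros((length, 4), dtype=np.int64)
        arr[:, 0] = 30  # monomorphic A background
        pile.counts[f"P{k}"] = arr
    child = np.zeros((length, 4), dtype=np.int64)
    child[:, 0] = 60
    pile.counts["C"] = child
    for pos, alleles in diag.items():
        for k in range(1, n_parents + 1):
            pile.counts[f"P{k}"][pos] = 0
        child[pos] = 0
        for base, parent in alleles.items():
            pile.counts[f"P{parent}"][pos, base_i[base]] = 30
            child[pos, base_i[base]] += 30
    for pos, base in novel.items():
        child[pos, base_i[base]] += 10
    for pos in masked_positions:
        for k in range(1, n_parents + 1):
            pile.counts[f"P{k}"][pos] = 0
        child[pos] = 0
    return hs.call_gene_sites(pile, protocol, hs.SnpModelParams())


class TestClassifyRead:
    def test_single_diagnostic_vote(self):
        calls = make_calls(100, diag={50: {"A": 1, "G": 2}})
        read = make_read("r", "C", 45, "A" * 10)
        rc = hs.classify_read(read, calls)
        assert rc.category == "parent1"
        assert rc.votes == {1: 1}
        assert not rc.conflict_flag and not rc.new_snp_flag

    def test_no_diagnostic_overlap_is_multi_parent(self):
        calls = make_calls(100, diag={90: {"A": 1, "G": 2}})
        read = make_read("r", "C", 0, "A" * 20)  # informative but non-diagnostic
        rc = hs.classify_read(read, calls)
        assert rc.category == CATEGORY_MULTI
        assert rc.votes == {}

    def test_only_masked_sites_is_unknown(self):
        calls = make_calls(30, masked_positions=set(range(10, 20)))
        read = make_read("r", "C", 12, "AAAA")
        rc = hs.classify_read(read, calls)
        assert rc.category == CATEGORY_UNKNOWN

    def test_conflicting_votes_demoted_with_flag(self):
        calls = make_calls(100, diag={10: {"A": 1, "C": 2}, 60: {"G": 1, "T": 2}})
        bases = ["A"] * 100
        bases[60] = "T"  # parent2's allele at the second site
        read = make_read("r", "C", 0, "".join(bases))
        rc = hs.classify_read(read, calls)
        assert rc.category == CATEGORY_MULTI
        assert rc.conflict_flag
        assert rc.votes == {1: 1, 2: 1}
        assert rc.diagnostic_hits == ((10, 1), (60, 2))

    def test_new_snp_flag_requires_pool_confirmation(self):
        calls = make_calls(100, novel={40: "T"})
        carrier = make_read("r1", "C", 35, "AAAAATAAAA")  # T at 40, confirmed
        rc = hs.classify_read(carrier, calls)
        assert rc.new_snp_flag and rc.category == CATEGORY_MULTI
        # a base unconfirmed by the pooled child pileup does not flag
        calls_plain = make_calls(100)
        rc2 = hs.classify_read(carrier, calls_plain)
        assert not rc2.new_snp_flag

    def test_position_without_site_call_is_error(self):
        calls = make_calls(20)
        read = make_read("r", "C", 15, "AAAAAAAA")
        with pytest.raises(ClassifyError):
            hs.classify_read(read, calls)

    def test_masking_moves_reads_away_from_parents_only(self):
        diag = {50: {"A": 1, "G": 2}}
        read = make_read("r", "C", 45, "A" * 10)
        before = hs.classify_read(read, make_calls(100, diag=diag))
        after = hs.classify_read(
            read, make_calls(100, diag=diag, masked_positions={50})
        )
        assert before.category == "parent1"
        assert after.category in (CATEGORY_MULTI, CATEGORY_UNKNOWN)

    def test_order_independence(self):
        calls = make_calls(100, diag={10: {"A": 1, "C": 2}, 60: {"G": 1, "T": 2}})
        reads = [
            make_read(f"r{i}", "C", i, "A" * 20) for i in range(0, 60, 7)
        ]
        fwd = [hs.classify_read(r, calls) for r in reads]
        rev = [hs.classify_read(r, calls) for r in reversed(reads)]
        assert fwd == rev[::-1]


class TestTally:
    def test_conservation(self, two_parent_protocol):
        classes = (
            [hs.ReadClass(f"a{i}", "g", "child_mRNA_1", "parent1", {1: 1}, False, False)
             for i in range(60)]
            + [hs.ReadClass(f"b{i}", "g", "child_mRNA_1", "parent2", {2: 1}, False, False)
               for i in range(25)]
            + [hs.ReadClass(f"c{i}", "g", "child_mRNA_1", CATEGORY_MULTI, {}, False, False)
               for i in range(10)]
            + [hs.ReadClass(f"d{i}", "g", "child_mRNA_1", CATEGORY_UNKNOWN, {}, False, False)
               for i in range(5)]
        )
        df = hs.tally(classes, two_parent_protocol)
        row = df.iloc[0]
        assert (row.parent1, row.parent2, row.multi_parent, row.unknown) == (60, 25, 10, 5)
        assert row.total == 100

    def test_zero_read_gene_emitted(self, two_parent_protocol):
        df = hs.tally([], two_parent_protocol, gene_ids=["gEmpty"])
        assert len(df) == 1
        assert df.iloc[0].total == 0

    def test_undeclared_sample_rejected(self, two_parent_protocol):
        bad = [hs.ReadClass("r", "g", "ghost", "parent1", {1: 1}, False, False)]
        with pytest.raises(ClassifyError, match="ghost"):
            hs.tally(bad, two_parent_protocol)
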