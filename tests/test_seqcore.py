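"""Translation tables, reverse complement and readthrough-aware ORFs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcescan.seqcore import (Contig, GeneCall, ReadthroughEvent,
                             TranslationTable, find_orfs, reverse_complement,
                             translate)

from conftest import random_dna_string
from oracles import orf_oracle

DNA = st.text(alphabet="ACGTN", min_size=1, max_size=120)


class TestTranslate:
    @pytest.mark.parametrize("seq,table,expected", [
        ("ATGAAATAG", TranslationTable.amber(), "MKO"),
        ("ATGTGAAAA", TranslationTable.opal(), "MUK"),
        ("ATGNNNAAA", TranslationTable.standard(), "MXK"),
        ("ATGTGATAG", TranslationTable.dual(), "MUO"),
        ("ATGTAGTGA", TranslationTable.standard(), "M**"),
    ])
    def test_readthrough_and_n_rules(self, seq, table, expected):
        assert translate(seq, table) == expected

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            translate("ATGA", TranslationTable.standard())

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            translate("ATGRRR", TranslationTable.standard())


class TestTranslationTable:
    def test_modes_assign_expected_letters(self):
        assert TranslationTable.amber().readthrough == {"TAG": "O"}
        assert TranslationTable.opal().readthrough == {"TGA": "U"}
        assert TranslationTable.dual().readthrough == {"TAG": "O", "TGA": "U"}

    def test_readthrough_must_target_stop_codons(self):
        with pytest.raises(ValueError):
            TranslationTable(readthrough={"ATG": "O"})
        with pytest.raises(ValueError):
            TranslationTable(readthrough={"TAG": "Z"})


class TestReverseComplement:
    def test_examples(self):
        assert reverse_complement("ATGC") == "GCAT"
        assert reverse_complement("NNAA") == "TTNN"

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            reverse_complement("ATXG")

    @settings(max_examples=100, derandomize=True)
    @given(DNA)
    def test_involution_preserves_length(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq
        assert len(reverse_complement(seq)) == len(seq)


class TestGeneCallInvariants:
    def test_span_must_be_codon_multiple(self):
        with pytest.raises(ValueError):
            GeneCall("c", 1, 11, "+", "MKK")

    def test_protein_length_must_match_span(self):
        with pytest.raises(ValueError):
            GeneCall("c", 1, 12, "+", "MK")

    def test_events_sorted_and_in_range(self):
        ev = ReadthroughEvent(4, "TAG", "O", 2)
        GeneCall("c", 1, 12, "+", "MOK", (ev,))
        with pytest.raises(ValueError):
            GeneCall("c", 1, 12, "+", "MOK",
                     (ReadthroughEvent(4, "TAG", "O", 9),))


class TestFindOrfs:
    def test_simple_orf(self):
        calls = find_orfs(Contig("c", "ATGAAAAAATAA"),
                          TranslationTable.standard(), min_len_codons=3)
        assert [(g.start, g.end, g.strand, g.protein) for g in calls] == [
            (1, 12, "+", "MKK")]
        assert calls[0].readthrough_events == ()

    def test_amber_readthrough_merges_coding_spans(self, rng):
        sense = "GCT" * 100
        contig = Contig("c", "ATG" + sense + "TAG" + sense + "TAA")
        standard = find_orfs(contig, TranslationTable.standard(), min_len_codons=3)
        amber = find_orfs(contig, TranslationTable.amber(), min_len_codons=3)
        plus_std = [g for g in standard if g.strand == "+"]
        plus_amb = [g for g in amber if g.strand == "+"]
        assert plus_std[0].end == 3 + 300 + 3  # stops at the TAG
        assert len(plus_amb) == 1
        g = plus_amb[0]
        assert g.end == len(contig.seq)
        assert [(e.letter, e.protein_pos) for e in g.readthrough_events] == [("O", 102)]
        assert g.protein[101] == "O"

    def test_exceeding_readthrough_budget_moves_the_start(self):
        # two TGAs between the first start and the stop, budget 1: the
        # reported ORF must begin after the first TGA
        seq = ("ATG" + "GCA" * 5 + "TGA" + "ATG" + "GCA" * 5 + "TGA"
               + "GCA" * 5 + "TAA")
        calls = find_orfs(Contig("c", seq), TranslationTable.opal(),
                          min_len_codons=3, max_readthrough=1)
        plus = [g for g in calls if g.strand == "+"]
        assert len(plus) == 1
        assert plus[0].start == 3 * 7 + 1  # the second ATG
        assert len(plus[0].readthrough_events) == 1

    @pytest.mark.parametrize("mode", ["standard", "amber", "opal", "dual"])
    def test_matches_bruteforce_oracle_on_random_contigs(self, mode):
        table = TranslationTable.from_mode(mode)
        rng = np.random.default_rng(77)
        for _ in range(25):
            n = int(rng.integers(1000, 10_000))
            seq = random_dna_string(rng, n)
            got = {(g.start, g.end, g.strand)
                   for g in find_orfs(Contig("c", seq), table,
                                      min_len_codons=30, max_readthrough=2)}
            assert got == orf_oracle(seq, table, 30, 2)

    def test_standard_orfs_nest_in_readthrough_orfs(self, rng):
        # readthrough merges coding spans; with an unconstrained budget
        # every standard ORF lies within exactly one dual-mode ORF
        seq = random_dna_string(rng, 9000)
        contig = Contig("c", seq)
        std = find_orfs(contig, TranslationTable.standard(), min_len_codons=20)
        dual = find_orfs(contig, TranslationTable.dual(), min_len_codons=20,
                         max_readthrough=10**6)
        for g in std:
            containers = [
                d for d in dual
                if d.strand == g.strand and d.start <= g.start and g.end <= d.end
                and (d.start - g.start) % 3 == 0]
            if g.strand == "+":
                stop = seq[g.end - 3 : g.end]
                downstream = seq[g.end:]
            else:
                stop = reverse_complement(seq[g.start - 1 : g.start + 2])
                downstream = reverse_complement(seq[: g.start - 1])
            if stop == "TAA":
                # hard stop in dual mode too: the container is the ORF itself
                assert len(containers) == 1
            else:
                # merged span must reach a downstream in-frame TAA; at the
                # contig edge there may be none and the merge runs off the end
                has_taa = any(downstream[i : i + 3] == "TAA"
                              for i in range(0, len(downstream) - 2, 3))
                assert len(containers) == (1 if has_taa else 0)

    def test_protein_roundtrips_through_genomic_span(self, rng):
        table = TranslationTable.dual()
        seq = random_dna_string(rng, 6000)
        contig = Contig("c", seq)
        for g in find_orfs(contig, table, min_len_codons=25):
            span = seq[g.start - 1 : g.end]
            if g.strand == "-":
                span = reverse_complement(span)
            assert translate(span, table)[:-1] == g.protein

    def test_results_sorted_and_min_len_enforced(self, rng):
        seq = random_dna_string(rng, 5000)
        calls = find_orfs(Contig("c", seq), TranslationTable.standard(),
                          min_len_codons=40)
        assert calls == sorted(calls, key=lambda g: (g.start, g.end, g.strand))
        assert all(len(g.protein) >= 40 for g in calls)
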