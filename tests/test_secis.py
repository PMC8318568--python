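"""SECIS hairpin search: scoring, oracle equivalence, planted recovery."""

import numpy as np
import pytest

from gcescan.secis import (find_hairpin, scan_secis,
                           LOOP_RANGE, MAX_MISMATCH, MAX_OFFSET, MIN_STEM,
                           SCORE_THRESHOLD, WINDOW_NT)
from gcescan.seqcore import (Contig, TranslationTable, find_orfs,
                             reverse_complement)
from gcescan.synthetic import PlantSpec, _build_selenoprotein, random_dna

from conftest import random_dna_string
from oracles import hairpin_oracle


def _gc_free_stem(rng, n):
    """A stem without G so no G.U wobble can blur the score arithmetic."""
    left = "".join(rng.choice(list("AC"), n))
    return left, reverse_complement(left)


class TestFindHairpin:
    def test_perfect_stem_scores_two_per_pair(self, rng):
        left, right = _gc_free_stem(rng, 12)
        seq = "CAA" + left + "AAACAA" + right + "CCAA"
        hp = find_hairpin(seq, min_stem=7, loop_range=(3, 14), max_mismatch=0)
        assert hp is not None
        assert (hp.start, hp.stem_bp, hp.loop_nt) == (3, 12, 6)
        assert hp.mismatches == 0 and hp.gu_pairs == 0
        assert hp.score == 24

    def test_homopolymer_has_no_hairpin(self):
        assert find_hairpin("A" * 80) is None

    def test_single_mismatch_gated_by_max_mismatch(self, rng):
        left, right = _gc_free_stem(rng, 10)
        # flip the middle pair of the right arm into a mismatch
        broken = right[:5] + ("C" if right[5] != "C" else "A") + right[6:]
        seq = "CCA" + left + "AACAAA" + broken + "CAC"
        with_mm = find_hairpin(seq, min_stem=10, loop_range=(3, 8), max_mismatch=1)
        assert with_mm is not None and with_mm.mismatches == 1
        assert with_mm.score == 2 * 9 - 2
        assert find_hairpin(seq, min_stem=10, loop_range=(3, 8),
                            max_mismatch=0) is None

    def test_extending_a_perfect_stem_adds_two(self, rng):
        left, right = _gc_free_stem(rng, 9)
        inner = "CCA" + left + "AACAAA" + right + "CAC"
        # wrap with one more Watson-Crick pair directly outside the stem
        extended = "CCT" + left + "AACAAA" + right + "AAC"
        hp0 = find_hairpin(inner, min_stem=7, max_mismatch=0)
        hp1 = find_hairpin(extended, min_stem=7, max_mismatch=0)
        assert hp1.stem_bp == hp0.stem_bp + 1
        assert hp1.score == hp0.score + 2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            find_hairpin("ACGX" * 10)
        with pytest.raises(ValueError):
            find_hairpin("ACGT" * 60)  # window above 200 nt
        with pytest.raises(ValueError):
            find_hairpin("ACGT" * 10, loop_range=(1, 5))

    @pytest.mark.parametrize("length", [80, 140, 200])
    def test_matches_exhaustive_placement_oracle(self, length):
        rng = np.random.default_rng(length)
        for _ in range(8):
            seq = random_dna_string(rng, length)
            got = find_hairpin(seq, min_stem=MIN_STEM, loop_range=LOOP_RANGE,
                               max_mismatch=MAX_MISMATCH, max_start=MAX_OFFSET)
            exp = hairpin_oracle(seq, MIN_STEM, LOOP_RANGE, MAX_MISMATCH,
                                 max_start=MAX_OFFSET)
            if exp is None:
                assert got is None
            else:
                score, i, n, loop, wc, gu, mm = exp
                assert (got.score, got.start, got.stem_bp, got.loop_nt,
                        got.wc_pairs, got.gu_pairs, got.mismatches) == (
                            score, i, n, loop, wc, gu, mm)

    def test_determinism(self, rng):
        seq = random_dna_string(rng, 150)
        assert find_hairpin(seq) == find_hairpin(seq)


def _planted_gene_and_contig(seed, plant=True):
    spec = PlantSpec(seed=seed)
    rng = np.random.default_rng(seed)
    feat = _build_selenoprotein(rng, spec, "g", plant)
    pad5 = random_dna(rng, 150, 0.41)
    pad3 = random_dna(rng, 150, 0.41)
    contig = Contig("c", pad5 + feat.dna + pad3)
    genes = find_orfs(contig, TranslationTable.opal())
    upos = feat.attrs["uga_protein_pos"]
    gene = next(g for g in genes
                if any(e.protein_pos == upos for e in g.readthrough_events))
    return feat, contig, gene


class TestScanSecis:
    def test_planted_hairpin_found_at_planted_offset(self):
        feat, contig, gene = _planted_gene_and_contig(1)
        hits = scan_secis(gene, contig)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.uga_protein_pos == feat.attrs["uga_protein_pos"]
        assert hit.offset_nt == feat.attrs["secis_offset"]
        assert hit.stem_bp == feat.attrs["secis_stem_bp"]
        assert hit.score >= SCORE_THRESHOLD

    def test_strand_symmetry(self):
        feat, contig, gene = _planted_gene_and_contig(2)
        flipped = Contig("c", reverse_complement(contig.seq))
        genes = find_orfs(flipped, TranslationTable.opal())
        upos = feat.attrs["uga_protein_pos"]
        minus = next(g for g in genes if g.strand == "-"
                     and any(e.protein_pos == upos for e in g.readthrough_events))
        plus_hits = scan_secis(gene, contig)
        minus_hits = scan_secis(minus, flipped)
        strip = lambda h: (h.uga_protein_pos, h.offset_nt, h.stem_bp,
                           h.loop_nt, h.mismatches, h.span_nt, h.score)
        assert [strip(h) for h in plus_hits] == [strip(h) for h in minus_hits]

    def test_terminal_stop_is_never_scanned(self):
        # a gene whose only UGA is the terminal stop has no U events
        seq = "TAA" + "ATG" + "GCT" * 80 + "TGA" + "C" * 40
        contig = Contig("c", seq)
        genes = find_orfs(contig, TranslationTable.standard(), min_len_codons=30)
        gene = next(g for g in genes if g.strand == "+")
        assert gene.readthrough_events == ()
        assert scan_secis(gene, contig) == []

    def test_decoy_windows_rarely_pass(self):
        called = total = 0
        for seed in range(40):
            feat, contig, gene = _planted_gene_and_contig(seed + 1000, plant=False)
            total += 1
            if scan_secis(gene, contig):
                called += 1
        assert called / total <= 0.05
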