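"""Cloverleaf folding, Pyl/Sec classification and the genome scan."""

import numpy as np
import pytest

from gcescan.seqcore import Contig, reverse_complement
from gcescan.synthetic import PlantSpec, _build_trna, random_dna
from gcescan.trna import (ArmLayout, ArmWindows, TRNACandidate, anticodon_of,
                          classify_trna, fold_cloverleaf, scan_genome_trnas,
                          SCORE_THRESHOLD)

from conftest import random_dna_string

SPEC = PlantSpec()


def _planted(seed, kind, anticodon):
    return _build_trna(np.random.default_rng(seed), SPEC, kind, kind, anticodon)


class TestFoldCloverleaf:
    @pytest.mark.parametrize("kind,anticodon,score", [
        ("standard", "GAA", 42), ("pyl", "CTA", 44), ("sec", "TCA", 46)])
    def test_roundtrip_recovers_constructed_layout(self, kind, anticodon, score):
        feat = _planted(5, kind, anticodon)
        res = fold_cloverleaf(feat.dna)
        assert res is not None
        layout, got_score, gu = res
        assert got_score == score
        assert anticodon_of(feat.dna, layout) == anticodon.replace("T", "U")
        if kind == "pyl":
            assert layout.ac_stem_bp == 6 and layout.spacer_nt == 1
        if kind == "sec":
            assert layout.var_is_arm

    def test_refold_never_scores_below_generating_layout(self):
        for seed in range(6):
            for kind, ac in (("standard", "GAA"), ("pyl", "CTA"), ("sec", "TCA")):
                feat = _planted(seed, kind, ac)
                expected = feat.attrs["pair_score"]
                res = fold_cloverleaf(feat.dna)
                assert res is not None and res[1] >= expected

    def test_unfoldable_homopolymer(self):
        assert fold_cloverleaf("A" * 80) is None

    def test_two_wobble_pairs_in_acceptor_recovered_with_relaxed_cap(self):
        feat = _planted(9, "standard", "GAA")
        seq = list(feat.dna)
        L = len(seq)
        # turn the two outermost acceptor pairs into G.U wobbles
        seq[0], seq[L - 1] = "G", "T"
        seq[1], seq[L - 2] = "T", "G"
        relaxed = ArmWindows(max_gu_per_stem=2)
        res = fold_cloverleaf("".join(seq), windows=relaxed)
        assert res is not None
        layout, score, gu = res
        assert layout.acceptor_bp >= 6
        assert gu >= 2  # the wobbles count as pairs, not mismatches
        assert score == 42

    def test_length_window_enforced(self):
        with pytest.raises(ValueError):
            fold_cloverleaf("ACGT" * 10)  # 40 nt < 60

    def test_rna_input_accepted(self):
        feat = _planted(3, "pyl", "CTA")
        rna = feat.dna.replace("T", "U")
        assert fold_cloverleaf(rna) is not None


class TestClassify:
    def _cand(self, anticodon, **layout_kw):
        defaults = dict(acceptor_bp=7, spacer_nt=2, d_stem_bp=4, d_loop_nt=8,
                        ac_stem_bp=5, ac_loop_nt=7, var_nt=4, var_is_arm=False,
                        t_stem_bp=5, t_loop_nt=7)
        defaults.update(layout_kw)
        layout = ArmLayout(**defaults)
        return TRNACandidate("c", 1, layout.total_nt, "+", anticodon, layout,
                             layout.pair_score, 0)

    def test_pyl_needs_cua_plus_hallmark(self):
        assert classify_trna(self._cand("CUA", ac_stem_bp=6)) == "pyl"
        assert classify_trna(self._cand("CUA", spacer_nt=1)) == "pyl"
        assert classify_trna(self._cand("CUA")) == "ambiguous"

    def test_sec_needs_uca_plus_variable_arm(self):
        assert classify_trna(self._cand("UCA", var_nt=16, var_is_arm=True)) == "sec"
        assert classify_trna(self._cand("UCA")) == "ambiguous"

    def test_standard_anticodons(self):
        assert classify_trna(self._cand("CAU")) == "standard"
        assert classify_trna(self._cand("GAA", ac_stem_bp=6)) == "standard"

    def test_class_depends_only_on_anticodon_and_layout(self):
        # permuting unrelated fields (coordinates, contig) never changes it
        a = self._cand("CUA", ac_stem_bp=6)
        b = TRNACandidate("other", 500, 500 + a.arm_layout.total_nt - 1, "-",
                          a.anticodon, a.arm_layout, a.pair_score, 1)
        assert classify_trna(a) == classify_trna(b)


class TestScanGenome:
    def test_planted_sec_and_pyl_recovered_at_planted_coordinates(self):
        rng = np.random.default_rng(21)
        sec = _planted(100, "sec", "TCA")
        pyl = _planted(101, "pyl", "CTA")
        bg = random_dna_string(rng, 20_000)
        seq = (bg[:6000] + "C" + sec.dna + "C" + bg[6000:14000]
               + "C" + reverse_complement(pyl.dna) + "C" + bg[14000:])
        cands = scan_genome_trnas([Contig("c", seq)])
        by_class = {c.trna_class: c for c in cands}
        assert "sec" in by_class and "pyl" in by_class
        assert (by_class["sec"].start, by_class["sec"].strand) == (6002, "+")
        pyl_start = 6000 + 2 + len(sec.dna) + 8000 + 1 + 1
        assert (by_class["pyl"].start, by_class["pyl"].strand) == (pyl_start, "-")
        assert by_class["sec"].anticodon == "UCA"
        assert by_class["pyl"].anticodon == "CUA"

    def test_planted_standard_trnas_never_classified_pyl_or_sec(self):
        rng = np.random.default_rng(31)
        feats = [_planted(200 + i, "standard", ac)
                 for i, ac in enumerate(("GAA", "CAT", "TGC"))]
        parts = [random_dna_string(rng, 3000)]
        for f in feats:
            parts += ["C", f.dna, "C", random_dna_string(rng, 3000)]
        cands = scan_genome_trnas([Contig("c", "".join(parts))])
        assert sum(1 for c in cands if c.trna_class == "standard") >= 3
        assert all(c.trna_class not in ("pyl", "sec") for c in cands)

    def test_mostly_empty_on_random_sequence(self):
        # threshold calibrated so pure random genomes are nearly always empty
        n_clean = 0
        for seed in range(30):
            rng = np.random.default_rng(9000 + seed)
            contig = Contig("c", random_dna_string(rng, 10_000))
            if not scan_genome_trnas([contig]):
                n_clean += 1
        assert n_clean >= 28

    def test_no_same_strand_overlaps(self, bench_full, scan_full):
        cands = scan_full.trnas
        for i, a in enumerate(cands):
            for b in cands[i + 1:]:
                if a.contig_id == b.contig_id and a.strand == b.strand:
                    assert a.end < b.start or b.end < a.start
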