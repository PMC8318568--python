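"""Pyl-site verification, selenoprotein calling, consensus, dereplication."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcescan.io import ReferenceProtein
from gcescan.recoding import (call_selenoproteins, consensus_sequence,
                              conserved_columns, dereplicate, verify_pyl_site)
from gcescan.secis import SECISHit
from gcescan.seqcore import GeneCall, ReadthroughEvent
from gcescan.synthetic import _random_aas

from oracles import consensus_oracle, conserved_oracle


def _pyl_protein(rng, length=120, opos=60):
    aas = list("M" + _random_aas(rng, length - 1))
    aas[opos - 1] = "O"
    return "".join(aas)


class TestVerifyPylSite:
    def test_identical_sequences(self, rng):
        prot = _pyl_protein(rng)
        rep = verify_pyl_site(prot, prot, window=20)
        assert rep.site_aligned
        assert rep.downstream_window_identity == 100.0
        assert rep.candidate_pyl_pos == rep.reference_pyl_pos == 60
        assert rep.candidate_length == rep.reference_length == 120

    def test_single_insertion_before_site_still_aligns(self, rng):
        ref = _pyl_protein(rng)
        cand = ref[:30] + "A" + ref[30:]  # O shifts from 60 to 61
        rep = verify_pyl_site(cand, ref, window=20)
        assert rep.candidate_pyl_pos == 61
        assert rep.reference_pyl_pos == 60
        assert rep.site_aligned
        assert rep.downstream_window_identity == 100.0

    def test_missing_pyl_errors_name_the_side(self, rng):
        prot = _pyl_protein(rng)
        plain = prot.replace("O", "K")
        with pytest.raises(ValueError, match="candidate"):
            verify_pyl_site(plain, prot)
        with pytest.raises(ValueError, match="reference"):
            verify_pyl_site(prot, plain)

    def test_truncated_tail_scores_low(self, rng):
        ref = _pyl_protein(rng, length=120, opos=60)
        cand = ref[:65]  # only 5 residues after the O site
        rep = verify_pyl_site(cand, ref, window=20)
        assert rep.downstream_window_identity <= 25.0


def _gene(contig, start, protein, letter="U", event_pos=None):
    event_pos = event_pos or protein.index(letter) + 1
    end = start + 3 * (len(protein) + 1) - 1
    return GeneCall(contig, start, end, "+", protein,
                    (ReadthroughEvent(start + 3 * (event_pos - 1),
                                      "TGA" if letter == "U" else "TAG",
                                      letter, event_pos),))


class TestCallSelenoproteins:
    def _hit(self, gene):
        return SECISHit(gene_id=gene.gene_id, uga_protein_pos=1, offset_nt=15,
                        stem_bp=15, loop_nt=6, mismatches=0, span_nt=36, score=30)

    def test_known_family_from_close_reference(self, rng):
        prot = "M" + _random_aas(rng, 150)
        prot = prot[:70] + "U" + prot[71:]
        gene = _gene("c", 1, prot)
        # a 96%-identical labeled reference
        ref = list(prot.replace("U", "C"))
        for i in rng.choice(np.arange(1, len(ref)), size=6, replace=False):
            ref[i] = "A" if ref[i] != "A" else "G"
        refs = [ReferenceProtein("r1", "".join(ref), label="fdh_like")]
        calls = call_selenoproteins([gene], [self._hit(gene)], refs)
        assert len(calls) == 1
        assert calls[0].group == "known_family"
        assert calls[0].family_label == "fdh_like"
        assert calls[0].best_reference_identity > 90.0

    def test_no_reference_yields_novel(self, rng):
        prot = ("M" + _random_aas(rng, 100))[:50] + "U" + _random_aas(rng, 50)
        gene = _gene("c", 1, prot)
        calls = call_selenoproteins([gene], [self._hit(gene)], [])
        assert [c.group for c in calls] == ["novel"]

    def test_gene_without_secis_hit_is_absent(self, rng):
        prot = ("M" + _random_aas(rng, 100))[:50] + "U" + _random_aas(rng, 50)
        gene = _gene("c", 1, prot)
        assert call_selenoproteins([gene], [], []) == []


class TestConsensus:
    def test_majority_and_tie_rules(self):
        assert consensus_sequence(["MKV", "MKV", "MRV"], 0.5) == "MKV"
        # a 50/50 tie fails the strict > threshold
        assert consensus_sequence(["MA", "MG"], 0.5) == "MX"
        assert consensus_sequence(["M-", "M-"], 0.5) == "M-"

    def test_identical_rows_return_the_row(self):
        for t in (0.3, 0.5, 0.99):
            assert consensus_sequence(["MKVA"] * 5, t) == "MKVA"

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError):
            consensus_sequence(["MK", "MKV"], 0.5)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.text(alphabet="ACDEFG-", min_size=8, max_size=8),
                    min_size=2, max_size=10),
           st.sampled_from([0.3, 0.5, 0.75]))
    def test_matches_counting_oracle(self, rows, threshold):
        assert consensus_sequence(rows, threshold) == consensus_oracle(rows, threshold)
        assert conserved_columns(rows, threshold) == conserved_oracle(rows, threshold)


class TestConservedColumns:
    def test_identical_rows_return_all_columns(self):
        assert conserved_columns(["MKVA"] * 4, 0.75) == [1, 2, 3, 4]

    def test_exact_threshold_fails_strict_inequality(self):
        rows = ["A", "A", "A", "G"]  # 3/4 agreement
        assert conserved_columns(rows, 0.75) == []


class TestDereplicate:
    def test_identical_sequences_collapse(self):
        reps, members = dereplicate({"a": "MKVLIEW" * 10, "b": "MKVLIEW" * 10}, 0.9)
        assert len(reps) == 1
        assert len(members) == 2
        assert set(members.values()) == set(reps)

    def test_distant_sequences_all_retained(self, rng):
        seqs = {f"s{i}": "M" + _random_aas(rng, 80) for i in range(5)}
        # random 80-mers sit far below 90% identity
        reps, _ = dereplicate(seqs, 0.9)
        assert sorted(reps) == sorted(seqs)

    def test_cluster_count_stable_under_input_permutation(self, rng):
        base = "M" + _random_aas(rng, 100)
        variants = {}
        for i in range(6):
            v = list(base)
            for j in rng.choice(np.arange(1, 101), size=3, replace=False):
                v[j] = "A" if v[j] != "A" else "C"
            variants[f"v{i}"] = "".join(v)
        variants["far"] = "M" + _random_aas(rng, 100)
        counts = set()
        for _ in range(5):
            keys = list(variants)
            rng.shuffle(keys)
            reps, _ = dereplicate({k: variants[k] for k in keys}, 0.9)
            counts.add(len(reps))
        assert counts == {2}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dereplicate({}, 0.9)
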