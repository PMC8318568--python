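"""Seeded synthetic genomes with planted genetic-code-expansion features.

The generator emulates, at desk scale and with machine-readable
ground truth, the features this pipeline detects in recoded
environmental MAGs: a ~41%-GC background carrying selenoprotein genes (in-frame TGA
plus a downstream perfect-stem SECIS hairpin), Pyl-containing TMA
methyltransferase genes (in-frame TAG at a conserved position — by
default residue 327 of 485, against an archaeal-style reference with
Pyl at 334 of 483), atypical Sec/Pyl tRNA genes, standard tRNAs, a
machinery annotation cassette with the cognate corrinoid protein fewer
than 10 genes from the methyltransferase anchor, and two decoy classes:
genes with an in-frame TGA but random downstream sequence, and
glycine-betaine-methyltransferase-like genes without an amber codon
(the classic Pyl-free mis-annotation).

Planted features are locally verified at build time (fold round-trips,
hairpin uniqueness, guard stops for exact ORF boundaries) so the truth
table is well defined; decoys are deliberately *not* screened against
the detectors — their call rate is the statistic being measured.
Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import secis as secis_mod
from .io import ReferenceProtein, write_fasta
from .machinery import AnnotationRow, write_annotation_tsv
from .secis import find_hairpin
from .seqcore import (Contig, TranslationTable, translate,
                      reverse_complement, PYRROLYSINE, SELENOCYSTEINE)
from .trna import ArmLayout, anticodon_of, classify_trna, fold_cloverleaf, TRNACandidate

__all__ = [
    "PlantSpec",
    "TruthFeature",
    "TruthTable",
    "SyntheticBenchmark",
    "generate",
    "mutate_copy",
    "default_benchmark",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_BASES = np.array(list("ACGT"))

_T11 = TranslationTable.standard().base_map
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in _T11.items():
    if _aa != "*":
        _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()

_STOPS = {"TAA", "TAG", "TGA"}


class CapacityError(ValueError):
    """Planted features do not fit in the requested genome length."""


@dataclass(frozen=True)
class PlantSpec:
    """Feature counts and study conditions for one synthetic benchmark.

    Defaults are the benchmark conditions: a 200-kb, 41%-GC genome with
    10 selenoproteins, 5 Pyl methyltransferases at the 327-of-485
    geometry, 5 TGA decoys, 3 glycine-betaine decoys, one Sec and one
    Pyl tRNA, 3 standard tRNAs and the machinery cassette.
    """

    n_selenoproteins: int = 10
    n_pyl: int = 5
    n_decoy_uga: int = 5
    n_decoy_gbmt: int = 3
    n_sec_trna: int = 1
    n_pyl_trna: int = 1
    n_standard_trna: int = 3
    machinery_cassette: bool = True
    genome_length: int = 200_000
    gc_fraction: float = 0.41
    n_contigs: int = 2
    seed: int = 0
    # Pyl-site geometry (1-based residue / protein length)
    pyl_position: int = 327
    pyl_length: int = 485
    ref_pyl_position: int = 334
    ref_pyl_length: int = 483
    # selenoprotein construction
    seleno_length_range: tuple[int, int] = (150, 250)
    secis_stem_bp: int = 15
    secis_loop_nt: int = 6
    secis_offset_range: tuple[int, int] = (12, 30)
    min_spacer_nt: int = 100

    def __post_init__(self) -> None:
        counts = (self.n_selenoproteins, self.n_pyl, self.n_decoy_uga,
                  self.n_decoy_gbmt, self.n_sec_trna, self.n_pyl_trna,
                  self.n_standard_trna)
        if any(c < 0 for c in counts):
            raise ValueError("feature counts must be >= 0")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.n_contigs < 1:
            raise ValueError("need at least one contig")
        if not 1 <= self.pyl_position <= self.pyl_length:
            raise ValueError("pyl_position outside protein")


@dataclass(frozen=True)
class TruthFeature:
    """Ground truth for one planted feature."""

    kind: str  # selenoprotein | pyl_methyltransferase | decoy_uga | decoy_gbmt | trna
    name: str
    contig: str
    start: int  # 1-based inclusive, start <= end
    end: int
    strand: str
    attrs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "name": self.name, "contig": self.contig,
                "start": self.start, "end": self.end, "strand": self.strand,
                "attrs": self.attrs}


@dataclass
class TruthTable:
    features: list[TruthFeature]
    cassette: dict[str, dict] = field(default_factory=dict)

    def of_kind(self, kind: str) -> list[TruthFeature]:
        return [f for f in self.features if f.kind == kind]

    def gene_intervals(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for f in self.features:
            out.setdefault(f.contig, []).append((f.start, f.end))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {"features": [f.to_dict() for f in self.features],
                   "cassette": self.cassette}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for f in self.features:
                ftype = "tRNA" if f.kind == "trna" else "CDS"
                attrs = [f"ID={f.name}", f"kind={f.kind}"]
                events = f.attrs.get("events")
                if events:
                    attrs.append("readthrough=" + ",".join(
                        f"{pos}:{codon}:{letter}" for pos, codon, letter, _ in events))
                if f.kind == "trna":
                    attrs.append(f"trna_class={f.attrs['trna_class']}")
                    attrs.append(f"anticodon={f.attrs['anticodon']}")
                fh.write("\t".join([f.contig, "gcescan_synthetic", ftype,
                                    str(f.start), str(f.end), ".", f.strand, ".",
                                    ";".join(attrs)]) + "\n")


@dataclass
class SyntheticBenchmark:
    """A generated genome plus its proteome, annotation and truth."""

    spec: PlantSpec
    contigs: list[Contig]
    proteome: dict[str, str]
    references: list[ReferenceProtein]
    annotation: list[AnnotationRow]
    truth: TruthTable

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "proteome": outdir / "proteins.faa",
            "references": outdir / "references.faa",
            "annotation": outdir / "annotation.tsv",
            "truth_gff3": outdir / "truth.gff3",
            "truth_json": outdir / "truth.json",
        }
        write_fasta({c.id: c.seq for c in self.contigs}, paths["genome"])
        write_fasta(self.proteome, paths["proteome"])
        write_fasta([(f"{r.id} family={r.label}", r.seq) for r in self.references],
                    paths["references"])
        write_annotation_tsv(self.annotation, paths["annotation"])
        self.truth.to_gff3(paths["truth_gff3"])
        self.truth.to_json(paths["truth_json"])
        return paths


# ---------------------------------------------------------------------------
# low-level sequence builders
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=p))


def _random_aas(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n)) if n > 0 else ""


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "M" + _random_aas(rng, n - 1)


def reverse_translate(protein: str, rng: np.random.Generator, gc: float) -> str:
    """Reverse-translate with synonymous codons weighted toward the
    target GC; O encodes as TAG, U as TGA."""
    base_p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    out = []
    for aa in protein:
        if aa == PYRROLYSINE:
            out.append("TAG")
            continue
        if aa == SELENOCYSTEINE:
            out.append("TGA")
            continue
        codons = _CODONS_BY_AA[aa]
        weights = np.array([base_p[c0] * base_p[c1] * base_p[c2]
                            for c0, c1, c2 in codons])
        out.append(codons[rng.choice(len(codons), p=weights / weights.sum())])
    return "".join(out)


def _substitute(rng: np.random.Generator, protein: str, rate: float,
                protected: set[int]) -> str:
    out = list(protein)
    for i in range(len(out)):
        if i in protected or out[i] in (PYRROLYSINE, SELENOCYSTEINE):
            continue
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.choice(len(choices))]
    return "".join(out)


def _in_frame_stop(dna: str) -> bool:
    return any(dna[i : i + 3] in _STOPS for i in range(0, len(dna) - 2, 3))


@dataclass
class _Feature:
    kind: str
    name: str
    dna: str                      # includes the guard TAA for gene features
    gene_rel: tuple[int, int]     # 0-based [start, end] of the feature proper
    protein: str = ""
    attrs: dict = field(default_factory=dict)
    events: list = field(default_factory=list)  # (rel_pos0, codon, letter, protein_pos)


def _build_selenoprotein(rng: np.random.Generator, spec: PlantSpec,
                         name: str, plant_hairpin: bool) -> _Feature:
    """A gene with an in-frame TGA; with ``plant_hairpin`` a perfect-stem
    SECIS follows it, otherwise the downstream window is plain random
    coding sequence (the decoy-UGA class)."""
    lo, hi = spec.seleno_length_range
    length = int(rng.integers(lo, hi + 1))
    upos = int(rng.integers(60, length - 45))
    prefix = random_protein(rng, upos - 1)
    n_down = length - upos  # codons after the U residue
    stem, loop = spec.secis_stem_bp, spec.secis_loop_nt
    if not plant_hairpin:
        # downstream of a decoy UGA is ordinary coding sequence
        down = reverse_translate(_random_aas(rng, n_down), rng, spec.gc_fraction)
        offset = None
    else:
        # the SECIS sits inside the coding sequence, so it is planted on
        # a codon boundary and padded to whole codons; the surrounding
        # codons are ordinary sense codons
        off_codons = int(rng.integers(spec.secis_offset_range[0] // 3,
                                      spec.secis_offset_range[1] // 3 + 1))
        offset = 3 * off_codons
        hp_nt = 2 * stem + loop
        pad = (3 - hp_nt % 3) % 3
        n_tail = n_down - off_codons - (hp_nt + pad) // 3
        if n_tail < 0:
            raise CapacityError("selenoprotein too short for its SECIS window")
        for _ in range(500):
            spacer = reverse_translate(_random_aas(rng, off_codons), rng,
                                       spec.gc_fraction)
            tail = reverse_translate(_random_aas(rng, n_tail), rng, spec.gc_fraction)
            stem5 = random_dna(rng, stem, 0.5)
            region = (stem5 + random_dna(rng, loop, spec.gc_fraction)
                      + reverse_complement(stem5) + random_dna(rng, pad, spec.gc_fraction))
            if _in_frame_stop(region):
                continue
            down = spacer + region + tail
            found = find_hairpin(down[: secis_mod.WINDOW_NT],
                                 max_start=secis_mod.MAX_OFFSET)
            if (found is None or found.start != offset
                    or found.stem_bp != stem or found.mismatches != 0
                    or found.score < secis_mod.SCORE_THRESHOLD):
                continue
            break
        else:  # pragma: no cover - would need a pathological spec
            raise CapacityError(f"could not build {name}")
    gene = reverse_translate(prefix, rng, spec.gc_fraction) + "TGA" + down + "TAA"
    dna = "TAA" + gene
    protein = translate(gene[:-3], TranslationTable.dual())
    assert len(protein) == length and protein[upos - 1] == SELENOCYSTEINE
    attrs = {"uga_protein_pos": upos, "length": length}
    if plant_hairpin:
        attrs.update(secis_offset=offset, secis_stem_bp=stem, secis_loop_nt=loop)
    return _Feature(
        kind="selenoprotein" if plant_hairpin else "decoy_uga",
        name=name, dna=dna, gene_rel=(3, len(dna) - 1), protein=protein,
        attrs=attrs, events=[(3 + 3 * (upos - 1), "TGA", SELENOCYSTEINE, upos)])


def _pyl_protected(spec: PlantSpec) -> set[int]:
    """0-based residue indices kept identical across Pyl variants: the
    start, the O site and a +/- conservation window around it."""
    o = spec.pyl_position - 1
    return {0} | set(range(max(0, o - 10), min(spec.pyl_length, o + 31)))


def _build_pyl_gene(rng: np.random.Generator, spec: PlantSpec, name: str,
                    template: str) -> _Feature:
    candidate = _substitute(rng, template, 0.05, _pyl_protected(spec))
    gene = reverse_translate(candidate, rng, spec.gc_fraction) + "TAA"
    dna = "TAA" + gene
    assert translate(gene[:-3], TranslationTable.dual()) == candidate
    return _Feature(
        kind="pyl_methyltransferase", name=name, dna=dna,
        gene_rel=(3, len(dna) - 1), protein=candidate,
        attrs={"pyl_protein_pos": spec.pyl_position, "length": spec.pyl_length},
        events=[(3 + 3 * (spec.pyl_position - 1), "TAG", PYRROLYSINE,
                 spec.pyl_position)])


def _build_gbmt_decoy(rng: np.random.Generator, spec: PlantSpec, name: str,
                      template: str) -> _Feature:
    """A methyltransferase-like homolog without an amber codon: the Pyl
    position holds lysine and the rest has drifted substantially."""
    protein = template.replace(PYRROLYSINE, "K")
    protein = _substitute(rng, protein, 0.25, {0})
    gene = reverse_translate(protein, rng, spec.gc_fraction) + "TAA"
    dna = "TAA" + gene
    return _Feature(kind="decoy_gbmt", name=name, dna=dna,
                    gene_rel=(3, len(dna) - 1), protein=protein,
                    attrs={"length": len(protein)})


def _build_pyl_reference(rng: np.random.Generator, spec: PlantSpec,
                         template: str) -> str:
    """Archaeal-style reference: same core as the template, shifted to
    the reference geometry (by default Pyl at 334 of 483) by scattered
    indels outside the conserved window around the Pyl site."""
    o = spec.pyl_position - 1
    ref = list(_substitute(rng, template, 0.08, _pyl_protected(spec)))
    prefix, suffix = ref[:o], ref[o + 1 :]
    n_ins = (spec.ref_pyl_position - 1) - len(prefix)
    n_del = len(suffix) - (spec.ref_pyl_length - spec.ref_pyl_position)
    if n_ins < 0 or n_del < 0 or n_del > len(suffix) - 40:
        raise ValueError("reference geometry incompatible with candidate geometry")
    for pos in sorted(rng.choice(np.arange(10, len(prefix) - 10), size=n_ins,
                                 replace=False), reverse=True):
        prefix.insert(int(pos), AA20[rng.choice(len(AA20))])
    for pos in sorted(rng.choice(np.arange(35, len(suffix)), size=n_del,
                                 replace=False), reverse=True):
        del suffix[int(pos)]
    ref_prot = "".join(prefix) + PYRROLYSINE + "".join(suffix)
    assert len(ref_prot) == spec.ref_pyl_length
    assert ref_prot.index(PYRROLYSINE) + 1 == spec.ref_pyl_position
    return ref_prot


_TRNA_LAYOUTS = {
    "standard": ArmLayout(7, 2, 4, 8, 5, 7, 4, False, 5, 7),
    "pyl": ArmLayout(7, 1, 4, 5, 6, 7, 4, False, 5, 7),
    "sec": ArmLayout(8, 2, 4, 7, 6, 7, 16, True, 5, 7),
}
_STANDARD_ANTICODONS = ("GAA", "CAT", "TGC", "GTT", "GCC")


def _make_stem(rng: np.random.Generator, n: int, gc: float,
               gu_probability: float = 0.5) -> tuple[str, str]:
    """A fully paired stem (5' strand, 3' strand); with probability
    ``gu_probability`` one position is a G.U wobble pair, as seen in
    real tRNA stems (never more than one, matching the fold model)."""
    gu_at = int(rng.integers(0, n)) if rng.random() < gu_probability else -1
    fives, threes = [], []
    for k in range(n):
        if k == gu_at:
            l, r = ("G", "T") if rng.random() < 0.5 else ("T", "G")
        else:
            l = rng.choice(_BASES, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            r = {"A": "T", "T": "A", "G": "C", "C": "G"}[l]
        fives.append(l)
        threes.append(r)
    return "".join(fives), "".join(reversed(threes))


def _build_trna(rng: np.random.Generator, spec: PlantSpec, name: str,
                kind: str, anticodon_dna: str) -> _Feature:
    layout = _TRNA_LAYOUTS[kind]
    gc = spec.gc_fraction
    for _ in range(500):
        acc5, acc3 = _make_stem(rng, layout.acceptor_bp, gc)
        d5, d3 = _make_stem(rng, layout.d_stem_bp, gc)
        c5, c3 = _make_stem(rng, layout.ac_stem_bp, gc)
        t5, t3 = _make_stem(rng, layout.t_stem_bp, gc)
        if layout.var_is_arm:
            v5, v3 = _make_stem(rng, 5, gc)
            var = v5 + random_dna(rng, layout.var_nt - 10, gc) + v3
        else:
            var = random_dna(rng, layout.var_nt, gc)
        seq = (acc5 + random_dna(rng, layout.spacer_nt, gc)
               + d5 + random_dna(rng, layout.d_loop_nt, gc) + d3
               + c5 + random_dna(rng, 2, gc) + anticodon_dna + random_dna(rng, 2, gc) + c3
               + var + t5 + random_dna(rng, layout.t_loop_nt, gc) + t3 + acc3)
        assert len(seq) == layout.total_nt
        folded = fold_cloverleaf(seq)
        if folded is None:
            continue
        got_layout, score, _gu = folded
        if score != layout.pair_score:
            continue  # an accidental extra-paired layout won; redraw
        cand = TRNACandidate(contig_id="x", start=1, end=len(seq), strand="+",
                             anticodon=anticodon_of(seq, got_layout),
                             arm_layout=got_layout, pair_score=score, gu_pairs=_gu)
        if classify_trna(cand) != kind:
            continue
        return _Feature(kind="trna", name=name, dna=seq,
                        gene_rel=(0, len(seq) - 1),
                        attrs={"trna_class": kind,
                               "anticodon": anticodon_dna.replace("T", "U"),
                               "pair_score": layout.pair_score})
    raise CapacityError(f"could not build tRNA {name}")  # pragma: no cover


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _place_features(rng: np.random.Generator, spec: PlantSpec,
                    features: list[_Feature]
                    ) -> tuple[list[Contig], list[tuple[_Feature, str, int, str]]]:
    """Returns contigs plus (feature, contig_id, 0-based offset, strand)."""
    order = list(rng.permutation(len(features)))
    per_contig: list[list[_Feature]] = [[] for _ in range(spec.n_contigs)]
    for slot, fi in enumerate(order):
        per_contig[slot % spec.n_contigs].append(features[fi])

    contig_len = spec.genome_length // spec.n_contigs
    contigs = []
    placements: list[tuple[_Feature, str, int, str]] = []
    gap_min = spec.min_spacer_nt
    for ci, feats in enumerate(per_contig):
        cid = f"contig_{ci + 1}"
        need = sum(len(f.dna) for f in feats) + gap_min * (len(feats) + 1)
        if need > contig_len:
            raise CapacityError(
                f"{cid}: planted features need {need} nt > {contig_len} nt available")
        extra = contig_len - need
        splits = rng.multinomial(extra, [1.0 / (len(feats) + 1)] * (len(feats) + 1))
        parts: list[str] = []
        pos = 0
        for f, extra_gap in zip(feats, splits[:-1]):
            gap = random_dna(rng, gap_min + int(extra_gap), spec.gc_fraction)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = f.dna if strand == "+" else reverse_complement(f.dna)
            if f.kind == "trna":
                # block accidental acceptor-stem extension into the flanks
                gap = gap[:-1] + "C"
            parts.append(gap)
            pos += len(gap)
            placements.append((f, cid, pos, strand))
            parts.append(placed)
            pos += len(placed)
            if f.kind == "trna":
                parts.append("C")
                pos += 1
        parts.append(random_dna(rng, gap_min + int(splits[-1]), spec.gc_fraction))
        contigs.append(Contig(id=cid, seq="".join(parts)))
    return contigs, placements


def _truth_for(feature: _Feature, contig_id: str, offset: int, strand: str
               ) -> TruthFeature:
    flen = len(feature.dna)
    rel_start, rel_end = feature.gene_rel
    if strand == "+":
        start, end = offset + rel_start + 1, offset + rel_end + 1
    else:
        start = offset + (flen - 1 - rel_end) + 1
        end = offset + (flen - 1 - rel_start) + 1
    attrs = dict(feature.attrs)
    if feature.events:
        events = []
        for rel_pos, codon, letter, ppos in feature.events:
            genomic = (offset + rel_pos + 1 if strand == "+"
                       else offset + (flen - 1 - rel_pos) + 1)
            events.append((genomic, codon, letter, ppos))
        attrs["events"] = events
    if feature.protein:
        attrs["protein_length"] = len(feature.protein)
    return TruthFeature(kind=feature.kind, name=feature.name, contig=contig_id,
                        start=start, end=end, strand=strand, attrs=attrs)


def _annotation_for(rng: np.random.Generator, spec: PlantSpec,
                    truths: list[TruthFeature]) -> tuple[list[AnnotationRow], dict]:
    """Annotation table mirroring planted gene order, with filler genes
    arranged so the machinery cassette sits around the first Pyl gene:
    pylB/C/D, pylS and metH immediately downstream, the cognate
    corrinoid protein at index distance 7 (< 10 genes) and ramA next to
    it; selA/selB and the duplicated cysA transporter elsewhere."""
    rows: list[AnnotationRow] = []
    cassette: dict[str, dict] = {}
    seleno_labels = ["selD", "fdhA", "hdrA"]
    seleno_seen = 0
    anchor_done = False
    fill = 0

    def filler(contig: str, index: int, labels: tuple[str, ...]) -> AnnotationRow:
        nonlocal fill
        fill += 1
        return AnnotationRow(gene_id=f"{contig}_fill{fill:03d}", contig_id=contig,
                             gene_index=index, family_accessions=labels)

    by_contig: dict[str, list[TruthFeature]] = {}
    for t in truths:
        if t.kind != "trna":
            by_contig.setdefault(t.contig, []).append(t)
    for contig in sorted(by_contig):
        index = 0
        for t in sorted(by_contig[contig], key=lambda f: f.start):
            index += int(rng.integers(1, 3))
            if t.kind == "selenoprotein":
                label = (seleno_labels[seleno_seen]
                         if seleno_seen < len(seleno_labels) else "hypothetical")
                seleno_seen += 1
                labels: tuple[str, ...] = (label,)
            elif t.kind == "pyl_methyltransferase":
                labels = ("mttB",)
            elif t.kind == "decoy_gbmt":
                labels = ("gbmt",)
            else:
                labels = ("hypothetical",)
            rows.append(AnnotationRow(gene_id=t.name, contig_id=contig,
                                      gene_index=index, family_accessions=labels))
            if (t.kind == "pyl_methyltransferase" and not anchor_done
                    and spec.machinery_cassette):
                anchor_done = True
                cassette["tma_methyltransferase"] = {
                    "gene_id": t.name, "contig": contig, "gene_index": index}
                locus = ["pylB", "pylC", "pylD", "pylS", "metH",
                         "hypothetical", "corrinoid", "ramA"]
                for dist, label in enumerate(locus, start=1):
                    row = filler(contig, index + dist, (label,))
                    rows.append(row)
                    if label != "hypothetical":
                        cassette[DEFAULT_LABEL_COMPONENT.get(label, label)] = {
                            "gene_id": row.gene_id, "contig": contig,
                            "gene_index": index + dist}
                index += len(locus)
        if spec.machinery_cassette and contig == sorted(by_contig)[0]:
            for labels in (("selA",), ("selB",), ("cysA",), ("cysA",)):
                index += 1
                rows.append(filler(contig, index, labels))
    rows.sort(key=lambda r: (r.contig_id, r.gene_index))
    return rows, cassette


# label -> machinery component name for cassette truth bookkeeping
DEFAULT_LABEL_COMPONENT = {
    "pylB": "pylB", "pylC": "pylC", "pylD": "pylD", "pylS": "pylS",
    "metH": "metH", "corrinoid": "pyl_corrinoid", "ramA": "ramA",
}


def generate(spec: PlantSpec) -> SyntheticBenchmark:
    """Generate a synthetic benchmark genome from ``spec`` (seeded)."""
    rng = np.random.default_rng(spec.seed)
    features: list[_Feature] = []

    template = random_protein(rng, spec.pyl_length)
    template = template[: spec.pyl_position - 1] + PYRROLYSINE + template[spec.pyl_position :]
    references = []
    if spec.n_pyl or spec.n_decoy_gbmt:
        references.append(ReferenceProtein(
            id="pyl_ref_archaeal", seq=_build_pyl_reference(rng, spec, template),
            label="tma_methyltransferase"))

    for i in range(spec.n_selenoproteins):
        features.append(_build_selenoprotein(rng, spec, f"seleno_{i + 1:02d}", True))
    for i in range(spec.n_pyl):
        features.append(_build_pyl_gene(rng, spec, f"pyl_mtase_{i + 1}", template))
    for i in range(spec.n_decoy_uga):
        features.append(_build_selenoprotein(rng, spec, f"decoy_uga_{i + 1}", False))
    for i in range(spec.n_decoy_gbmt):
        features.append(_build_gbmt_decoy(rng, spec, f"decoy_gbmt_{i + 1}", template))
    for i in range(spec.n_sec_trna):
        features.append(_build_trna(rng, spec, f"sec_trna_{i + 1}", "sec", "TCA"))
    for i in range(spec.n_pyl_trna):
        features.append(_build_trna(rng, spec, f"pyl_trna_{i + 1}", "pyl", "CTA"))
    for i in range(spec.n_standard_trna):
        anticodon = _STANDARD_ANTICODONS[i % len(_STANDARD_ANTICODONS)]
        features.append(_build_trna(rng, spec, f"std_trna_{i + 1}", "standard", anticodon))

    # the first three planted selenoproteins double as labeled references
    # (perturbed, so best-hit identities are high but not 100)
    seleno_feats = [f for f in features if f.kind == "selenoprotein"]
    for ref_i, f in enumerate(seleno_feats[:3]):
        label = ["selD", "fdhA", "hdrA"][ref_i]
        perturbed = _substitute(rng, f.protein, 0.04, {0, f.attrs["uga_protein_pos"] - 1})
        references.append(ReferenceProtein(
            id=f"seleno_ref_{label}", seq=perturbed, label=label))

    contigs, placements = _place_features(rng, spec, features)
    truths = [_truth_for(f, cid, off, strand) for f, cid, off, strand in placements]
    truths.sort(key=lambda t: (t.contig, t.start))
    annotation, cassette = _annotation_for(rng, spec, truths)
    proteome = {f.name: f.protein for f in features if f.protein}
    return SyntheticBenchmark(spec=spec, contigs=contigs, proteome=proteome,
                              references=references, annotation=annotation,
                              truth=TruthTable(features=truths, cassette=cassette))


def default_benchmark(seed: int = 0) -> SyntheticBenchmark:
    return generate(PlantSpec(seed=seed))


def mutate_copy(contigs: Sequence[Contig], substitution_rate: float, seed: int,
                exclude: Mapping[str, Sequence[tuple[int, int]]] | None = None
                ) -> list[Contig]:
    """Per-site independent substitutions (no indels), seeded.

    Each selected site is replaced by a uniformly chosen *different*
    base; N sites are left alone.  ``exclude`` maps contig ids to
    1-based inclusive intervals shielded from mutation (e.g. planted
    gene spans, so protein-level truths stay valid).
    """
    if not 0 <= substitution_rate < 1:
        raise ValueError("substitution_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    out = []
    for contig in contigs:
        arr = np.array(list(contig.seq))
        mask = rng.random(len(arr)) < substitution_rate
        mask &= arr != "N"
        if exclude and contig.id in exclude:
            for s, e in exclude[contig.id]:
                mask[s - 1 : e] = False
        idx = np.nonzero(mask)[0]
        if len(idx):
            old = np.array([code[b] for b in arr[idx]])
            new = (old + rng.integers(1, 4, size=len(idx))) % 4
            arr[idx] = _BASES[new]
        out.append(Contig(id=contig.id, seq="".join(arr)))
    return out
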