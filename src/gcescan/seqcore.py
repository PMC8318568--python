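"""Core sequence types, readthrough-aware translation and ORF enumeration.

Natural genetic code expansion reassigns stop codons: pyrrolysine (Pyl,
one-letter code ``O``) is inserted at in-frame UAG (amber) codons and
selenocysteine (Sec, ``U``) at in-frame UGA (opal) codons.  A conventional
gene caller truncates such genes at the recoded stop; this module provides
a :class:`TranslationTable` that can carry amber/opal readthrough
reassignments and an exhaustive ORF enumerator that records every
readthrough event it passes through, so downstream evidence (SECIS
elements, Pyl active-site conservation) can be attached to the right
residue of the right protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data import CodonTable as _CodonTable

__all__ = [
    "Contig",
    "TranslationTable",
    "ReadthroughEvent",
    "GeneCall",
    "reverse_complement",
    "translate",
    "find_orfs",
    "PYRROLYSINE",
    "SELENOCYSTEINE",
    "START_CODONS",
]

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PYRROLYSINE = "O"
SELENOCYSTEINE = "U"
STOP = "*"

#: Bacterial (table 11) start codons.  GTG/TTG starts are translated
#: literally (V/L) so that re-translating a gene's genomic span always
#: reproduces its protein field.
START_CODONS = ("ATG", "GTG", "TTG")

_STOP_CODONS = ("TAA", "TAG", "TGA")


def _table11() -> dict[str, str]:
    """The 64-codon bacterial code (NCBI table 11), stops mapped to ``*``."""
    t11 = _CodonTable.unambiguous_dna_by_id[11]
    base = dict(t11.forward_table)
    for codon in t11.stop_codons:
        base[codon] = STOP
    return base


_BASE_MAP_11 = _table11()


@dataclass(frozen=True)
class Contig:
    """A DNA sequence record (one MAG contig).

    ``seq`` must be a non-empty uppercase string over ``{A,C,G,T,N}``.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.id!r}: invalid characters {sorted(bad)!r} "
                "(expected uppercase A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TranslationTable:
    """A 64-codon map plus stop-codon readthrough reassignments.

    ``base_map`` follows bacterial (table 11) semantics with stop codons
    mapped to ``*``.  ``readthrough`` maps a subset of the stop codons to
    the non-canonical letter inserted there: amber mode assigns
    ``TAG -> O`` (pyrrolysine), opal mode ``TGA -> U`` (selenocysteine),
    dual mode both.  TAA is never reassigned by the built-in modes.
    """

    base_map: Mapping[str, str] = field(default_factory=lambda: dict(_BASE_MAP_11))
    readthrough: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.base_map) != 64 or set(self.base_map) != {
            a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
        }:
            raise ValueError("base_map must cover exactly the 64 DNA codons")
        for codon, letter in self.readthrough.items():
            if codon not in _STOP_CODONS:
                raise ValueError(f"readthrough codon {codon!r} is not a stop codon")
            if self.base_map[codon] != STOP:
                raise ValueError(f"readthrough codon {codon!r} is not STOP in base_map")
            if letter not in (PYRROLYSINE, SELENOCYSTEINE):
                raise ValueError(f"readthrough letter {letter!r} must be O or U")

    # -- canonical modes ---------------------------------------------------
    @classmethod
    def standard(cls) -> "TranslationTable":
        return cls()

    @classmethod
    def amber(cls) -> "TranslationTable":
        """TAG read through as pyrrolysine (O)."""
        return cls(readthrough={"TAG": PYRROLYSINE})

    @classmethod
    def opal(cls) -> "TranslationTable":
        """TGA read through as selenocysteine (U)."""
        return cls(readthrough={"TGA": SELENOCYSTEINE})

    @classmethod
    def dual(cls) -> "TranslationTable":
        """Both amber (TAG->O) and opal (TGA->U) readthrough."""
        return cls(readthrough={"TAG": PYRROLYSINE, "TGA": SELENOCYSTEINE})

    @classmethod
    def from_mode(cls, mode: str) -> "TranslationTable":
        try:
            return {"standard": cls.standard, "amber": cls.amber,
                    "opal": cls.opal, "dual": cls.dual}[mode]()
        except KeyError:
            raise ValueError(f"unknown table mode {mode!r}") from None

    def is_hard_stop(self, codon: str) -> bool:
        return self.base_map.get(codon) == STOP and codon not in self.readthrough


@dataclass(frozen=True)
class ReadthroughEvent:
    """One recoded stop codon inside a gene.

    ``genomic_pos`` is the 1-based position of the codon's first base in
    reading direction (for minus-strand genes this is the larger
    coordinate of the codon).
    """

    genomic_pos: int
    codon: str
    letter: str
    protein_pos: int


@dataclass(frozen=True)
class GeneCall:
    """An ORF with recorded readthrough events.

    ``start``/``end`` are 1-based inclusive genomic coordinates with
    ``start <= end`` regardless of strand; the span includes the terminal
    stop codon, while ``protein`` excludes it.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    protein: str
    readthrough_events: tuple[ReadthroughEvent, ...] = ()

    def __post_init__(self) -> None:
        span = self.end - self.start + 1
        if span % 3:
            raise ValueError("gene span must be divisible by 3")
        if len(self.protein) != span // 3 - 1:
            raise ValueError("protein length must equal span/3 - 1")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        for ev in self.readthrough_events:
            if not 1 <= ev.protein_pos <= len(self.protein):
                raise ValueError("event protein_pos outside protein")
        positions = [ev.protein_pos for ev in self.readthrough_events]
        if positions != sorted(positions):
            raise ValueError("events must be sorted by protein_pos")

    @property
    def gene_id(self) -> str:
        return f"{self.contig_id}|{self.start}-{self.end}({self.strand})"

    def events_with_letter(self, letter: str) -> tuple[ReadthroughEvent, ...]:
        return tuple(ev for ev in self.readthrough_events if ev.letter == letter)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} (N maps to N)."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, table: TranslationTable | None = None) -> str:
    """Translate ``seq`` under ``table`` without terminating mid-sequence.

    Readthrough codons yield their reassigned letter (O/U); hard stops
    yield ``*``; any codon containing N yields X.  The caller supplies the
    ORF span, so translation runs to the end of the sequence.
    """
    if table is None:
        table = TranslationTable.standard()
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)!r}")
    out = []
    rt = table.readthrough
    base = table.base_map
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in rt:
            out.append(rt[codon])
        else:
            out.append(base[codon])
    return "".join(out)


def _scan_frames(oriented: str, table: TranslationTable,
                 min_len_codons: int, max_readthrough: int):
    """Yield (frame, start_codon_idx, stop_codon_idx, rt_codon_idxs).

    Codon indices are 0-based within each frame of ``oriented``.  One ORF
    is reported per hard (non-readthrough) stop: the leftmost start codon
    after the previous hard stop whose span passes through at most
    ``max_readthrough`` readthrough codons and is long enough.
    """
    n = len(oriented)
    rt_set = frozenset(table.readthrough)
    for frame in range(3):
        starts: list[int] = []
        rts: list[int] = []
        k = 0
        for pos in range(frame, n - 2, 3):
            codon = oriented[pos : pos + 3]
            if codon in rt_set:
                rts.append(k)
            elif table.base_map.get(codon) == STOP:
                for s in starts:
                    n_rt = sum(1 for r in rts if r > s)
                    if n_rt > max_readthrough:
                        continue
                    if k - s >= min_len_codons:
                        yield frame, s, k, [r for r in rts if r > s]
                    # later starts only shorten the span
                    break
                starts.clear()
                rts.clear()
            if codon in START_CODONS:
                starts.append(k)
            k += 1


def find_orfs(contig: Contig, table: TranslationTable,
              min_len_codons: int = 60, max_readthrough: int = 2) -> list[GeneCall]:
    """Enumerate readthrough-aware ORFs on both strands of ``contig``.

    ORFs begin at a bacterial start codon (ATG/GTG/TTG), end at a hard
    stop, and pass through at most ``max_readthrough`` readthrough
    codons, each recorded as a :class:`ReadthroughEvent`.  The longest
    ORF per terminal stop (leftmost qualifying start in reading
    direction) is reported; results are sorted by (start, end, strand).
    Contigs are treated as linear fragments — no wrap-around.
    """
    if min_len_codons < 2:
        raise ValueError("min_len_codons must be >= 2")
    if max_readthrough < 0:
        raise ValueError("max_readthrough must be >= 0")
    L = len(contig.seq)
    calls: list[GeneCall] = []
    for strand, oriented in (("+", contig.seq), ("-", reverse_complement(contig.seq))):
        for frame, s, e, rts in _scan_frames(oriented, table,
                                             min_len_codons, max_readthrough):
            o_start = frame + 3 * s          # 0-based, first base of start codon
            o_end = frame + 3 * e + 2        # 0-based, last base of stop codon
            coding = oriented[o_start : o_end + 1 - 3]
            protein = translate(coding, table)
            events = []
            for r in rts:
                o_pos = frame + 3 * r
                codon = oriented[o_pos : o_pos + 3]
                genomic = o_pos + 1 if strand == "+" else L - o_pos
                events.append(ReadthroughEvent(
                    genomic_pos=genomic, codon=codon,
                    letter=table.readthrough[codon], protein_pos=r - s + 1))
            if strand == "+":
                g_start, g_end = o_start + 1, o_end + 1
            else:
                g_start, g_end = L - o_end, L - o_start
            calls.append(GeneCall(
                contig_id=contig.id, start=g_start, end=g_end, strand=strand,
                protein=protein, readthrough_events=tuple(events)))
    calls.sort(key=lambda g: (g.start, g.end, g.strand))
    return calls


def find_orfs_genome(contigs: Iterable[Contig], table: TranslationTable,
                     min_len_codons: int = 60, max_readthrough: int = 2) -> list[GeneCall]:
    """`find_orfs` over a genome, sorted by (contig, start)."""
    out: list[GeneCall] = []
    for contig in contigs:
        out.extend(find_orfs(contig, table, min_len_codons, max_readthrough))
    out.sort(key=lambda g: (g.contig_id, g.start, g.end, g.strand))
    return out
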