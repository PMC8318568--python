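"""SECIS-like hairpin detection downstream of in-frame UGA codons.

In bacteria, selenocysteine insertion at an in-frame UGA requires a
Sec insertion sequence (SECIS): a hairpin of roughly 50 nt starting
immediately downstream of the recoded codon.  The scan here is a
deliberately transparent structural model: an exhaustive search over
all contiguous stem/loop placements inside a bounded window, scoring

    score = 2 * (Watson-Crick pairs) + 1 * (G.U pairs) - 2 * (mismatches)

with bulges modeled only as scored mismatches.  Exhaustiveness keeps
the scan exactly reproducible by a brute-force oracle; there is no
free-energy minimization and no archaeal/eukaryotic SECIS model.

The default score threshold is calibrated on random sequence so that a
whole-genome scan (thousands of downstream windows) stays essentially
free of spurious hits; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqcore import Contig, GeneCall, SELENOCYSTEINE, reverse_complement

__all__ = [
    "Hairpin",
    "SECISHit",
    "find_hairpin",
    "scan_secis",
    "MIN_STEM",
    "LOOP_RANGE",
    "MAX_MISMATCH",
    "SCORE_THRESHOLD",
    "MAX_OFFSET",
    "WINDOW_NT",
]

MIN_STEM = 7
LOOP_RANGE = (3, 14)
MAX_MISMATCH = 1
#: Calibrated on random 75-nt windows at 41% GC (see docs/methods.md).
SCORE_THRESHOLD = 28
#: The hairpin must start within this many nt of the UGA 3' end.
MAX_OFFSET = 40
#: Downstream window extracted after the UGA codon.
WINDOW_NT = 75

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# pair classification tables over base codes (N never pairs)
_WC = np.zeros((5, 5), dtype=bool)
for _x, _y in ((0, 3), (3, 0), (1, 2), (2, 1)):
    _WC[_x, _y] = True
_GU = np.zeros((5, 5), dtype=bool)
for _x, _y in ((2, 3), (3, 2)):
    _GU[_x, _y] = True


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid character {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class Hairpin:
    """A stem-loop placement inside a scanned window (0-based start)."""

    start: int
    stem_bp: int
    loop_nt: int
    wc_pairs: int
    gu_pairs: int
    mismatches: int
    score: int

    @property
    def span_nt(self) -> int:
        return 2 * self.stem_bp + self.loop_nt


@dataclass(frozen=True)
class SECISHit:
    """A passing hairpin downstream of a U readthrough event."""

    gene_id: str
    uga_protein_pos: int
    offset_nt: int
    stem_bp: int
    loop_nt: int
    mismatches: int
    span_nt: int
    score: int


def find_hairpin(seq: str, min_stem: int = MIN_STEM,
                 loop_range: tuple[int, int] = LOOP_RANGE,
                 max_mismatch: int = MAX_MISMATCH,
                 max_start: int | None = None) -> Hairpin | None:
    """Best-scoring contiguous stem-loop placement in ``seq``.

    All (start, stem, loop) placements are scanned; a placement is
    admissible when its loop length lies in ``loop_range``, it carries
    at most ``max_mismatch`` mismatched stem positions, and (when
    ``max_start`` is given) it starts at or before that 0-based offset.
    Ties are broken toward smaller start, then longer stem, then
    smaller loop.  Returns None when nothing is admissible.
    """
    L = len(seq)
    if L > 200:
        raise ValueError("find_hairpin windows are limited to 200 nt")
    lo, hi = loop_range
    if lo < 3 or hi < lo:
        # hairpin loops below 3 nt are sterically impossible
        raise ValueError("loop_range lower bound must be >= 3 and hi >= lo")
    if min_stem < 1:
        raise ValueError("min_stem must be >= 1")
    if L < 2 * min_stem + lo:
        return None
    code = _encode(seq)

    wc = _WC[code[:, None], code[None, :]]
    gu = _GU[code[:, None], code[None, :]]
    # cumulate pair counts inward along anti-diagonals:
    # C[i, j] = pairs on (i, j), (i+1, j-1), ... down to the diagonal
    cw = np.zeros((L + 1, L + 2), dtype=np.int32)
    cg = np.zeros((L + 1, L + 2), dtype=np.int32)
    for d in range(2, L):  # d = j - i
        m = L - d
        cw[:m, d] = wc[np.arange(m), np.arange(d, L)] + cw[1 : m + 1, d - 2]
        cg[:m, d] = gu[np.arange(m), np.arange(d, L)] + cg[1 : m + 1, d - 2]

    best: tuple | None = None  # (-score, start, -stem, loop, wc, gu, mm)
    max_stem = (L - lo) // 2
    for n in range(min_stem, max_stem + 1):
        for loop in range(lo, hi + 1):
            d = 2 * n + loop - 1  # j - i for the outermost pair
            m = L - d
            if m <= 0:
                continue
            i = np.arange(m)
            w = cw[:m, d] - cw[n : n + m, d - 2 * n]
            g = cg[:m, d] - cg[n : n + m, d - 2 * n]
            mm = n - w - g
            score = 2 * w + g - 2 * mm
            ok = mm <= max_mismatch
            if max_start is not None:
                ok &= i <= max_start
            if not ok.any():
                continue
            idx = np.nonzero(ok)[0]
            sc = score[idx]
            top = idx[np.argmax(sc)]
            cand = (-int(score[top]), int(top), -n, loop,
                    int(w[top]), int(g[top]), int(mm[top]))
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    neg_score, start, neg_stem, loop, w, g, mm = best
    return Hairpin(start=start, stem_bp=-neg_stem, loop_nt=loop,
                   wc_pairs=w, gu_pairs=g, mismatches=mm, score=-neg_score)


def _downstream_window(gene: GeneCall, contig: Contig, genomic_pos: int,
                       window_nt: int) -> str:
    """Window of up to ``window_nt`` nt after the codon, in reading direction.

    ``genomic_pos`` is the 1-based first base of the codon in reading
    direction (the larger coordinate on the minus strand).
    """
    seq = contig.seq
    if gene.strand == "+":
        start0 = genomic_pos + 2  # 0-based index just after the codon
        return seq[start0 : start0 + window_nt]
    end0 = genomic_pos - 3  # exclusive 0-based end of the upstream slice
    return reverse_complement(seq[max(0, end0 - window_nt) : end0])


def scan_secis(gene: GeneCall, contig: Contig,
               window_nt: int = WINDOW_NT,
               min_stem: int = MIN_STEM,
               loop_range: tuple[int, int] = LOOP_RANGE,
               max_mismatch: int = MAX_MISMATCH,
               max_offset: int = MAX_OFFSET,
               score_threshold: int = SCORE_THRESHOLD) -> list[SECISHit]:
    """SECIS hits for every U readthrough event of ``gene``.

    For each selenocysteine event the strand-aware downstream window is
    extracted and the best admissible hairpin is kept when its score
    passes the threshold.  The terminal stop codon carries no event, so
    it is never scanned; a gene without U events yields an empty list.
    """
    hits = []
    for event in gene.events_with_letter(SELENOCYSTEINE):
        window = _downstream_window(gene, contig, event.genomic_pos, window_nt)
        if len(window) < 2 * min_stem + loop_range[0]:
            continue
        hp = find_hairpin(window, min_stem=min_stem, loop_range=loop_range,
                          max_mismatch=max_mismatch, max_start=max_offset)
        if hp is not None and hp.score >= score_threshold:
            hits.append(SECISHit(
                gene_id=gene.gene_id, uga_protein_pos=event.protein_pos,
                offset_nt=hp.start, stem_bp=hp.stem_bp, loop_nt=hp.loop_nt,
                mismatches=hp.mismatches, span_nt=hp.span_nt, score=hp.score))
    return hits


def scan_secis_genome(genes: Sequence[GeneCall], contigs: Iterable[Contig],
                      **params) -> list[SECISHit]:
    """`scan_secis` over all genes of a genome."""
    by_id = {c.id: c for c in contigs}
    hits: list[SECISHit] = []
    for gene in genes:
        if gene.events_with_letter(SELENOCYSTEINE):
            hits.extend(scan_secis(gene, by_id[gene.contig_id], **params))
    return hits
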