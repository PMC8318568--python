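"""tRNA detection by constrained cloverleaf folding; Pyl/Sec classification.

The pyrrolysine and selenocysteine tRNAs are recognizable by structure
alone: the Pyl tRNA carries a CUA (amber-suppressor) anticodon together
with a 6-bp anticodon stem and a single nucleotide between the acceptor
stem and the D arm; the Sec tRNA carries a UCA (opal-suppressor)
anticodon and, instead of the usual ~4-nt variable loop, a long variable
arm between the anticodon arm and the T arm.

Folding is an exhaustive search over arm-length windows bracketing
canonical tRNA dimensions plus those deviations.  Every stem must be
fully paired (Watson-Crick or G.U wobble — wobble pairs are normal in
tRNA stems, but at most one per stem by default: letting them cluster
makes random sequence fold as well as real tRNAs); ``pair_score``
counts the nucleotides engaged in the four cloverleaf stems (2 per
base pair).  The variable arm's internal stem is
detected for classification but does not enter ``pair_score``.

The genome scan uses a layered dynamic program over per-position arm
feasibility tables, which is exactly equivalent to enumerating every
legal layout at every position, then re-derives the full layout of each
above-threshold site with the exhaustive per-site fold.  The default
score threshold is calibrated on random 41%-GC sequence (see
``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .seqcore import Contig, reverse_complement

__all__ = [
    "ArmWindows",
    "ArmLayout",
    "TRNACandidate",
    "fold_cloverleaf",
    "classify_trna",
    "scan_genome_trnas",
    "DEFAULT_WINDOWS",
    "SCORE_THRESHOLD",
]

#: Calibrated on random 20-kb genomes at 41% GC (see docs/methods.md).
SCORE_THRESHOLD = 42

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_GU = {("G", "T"), ("T", "G")}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_PAIRABLE = np.zeros((5, 5), dtype=bool)
for _x, _y in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _PAIRABLE[_x, _y] = True
_GU_TABLE = np.zeros((5, 5), dtype=bool)
for _x, _y in ((2, 3), (3, 2)):
    _GU_TABLE[_x, _y] = True

_NEG = -(10 ** 6)


@dataclass(frozen=True)
class ArmWindows:
    """Inclusive length windows for each cloverleaf element (nt or bp).

    Defaults bracket canonical tRNA dimensions plus the Pyl hallmarks
    (6-bp anticodon stem, 1-nt acceptor-to-D spacer) and the Sec
    variable arm.  The anticodon loop is fixed at 7 nt with the
    anticodon at loop positions 3-5.
    """

    acceptor: tuple[int, int] = (6, 9)
    spacer: tuple[int, int] = (1, 3)
    d_stem: tuple[int, int] = (3, 4)
    d_loop: tuple[int, int] = (4, 12)
    ac_stem: tuple[int, int] = (5, 6)
    ac_loop: int = 7
    var: tuple[int, int] = (3, 23)
    var_arm_min_nt: int = 10
    var_arm_min_stem: int = 3
    t_stem: tuple[int, int] = (4, 5)
    t_loop: tuple[int, int] = (5, 9)
    length: tuple[int, int] = (60, 120)
    #: at most this many G.U wobble pairs per stem (wobble pairs are
    #: normal in tRNA stems but rarely cluster; capping them is what
    #: separates real cloverleaves from random foldable sequence)
    max_gu_per_stem: int = 1


DEFAULT_WINDOWS = ArmWindows()


@dataclass(frozen=True)
class ArmLayout:
    """Cloverleaf decomposition (stem lengths in bp, loops in nt)."""

    acceptor_bp: int
    spacer_nt: int
    d_stem_bp: int
    d_loop_nt: int
    ac_stem_bp: int
    ac_loop_nt: int
    var_nt: int
    var_is_arm: bool
    t_stem_bp: int
    t_loop_nt: int

    @property
    def total_nt(self) -> int:
        return (2 * self.acceptor_bp + self.spacer_nt + 2 * self.d_stem_bp
                + self.d_loop_nt + 2 * self.ac_stem_bp + self.ac_loop_nt
                + self.var_nt + 2 * self.t_stem_bp + self.t_loop_nt)

    @property
    def pair_score(self) -> int:
        """Nucleotides engaged in the four cloverleaf stems."""
        return 2 * (self.acceptor_bp + self.d_stem_bp
                    + self.ac_stem_bp + self.t_stem_bp)


@dataclass(frozen=True)
class TRNACandidate:
    """A folded tRNA gene candidate (1-based inclusive coordinates)."""

    contig_id: str
    start: int
    end: int
    strand: str
    anticodon: str  # RNA, coding-strand reading
    arm_layout: ArmLayout
    pair_score: int
    gu_pairs: int
    trna_class: str = ""  # standard | pyl | sec | ambiguous


def _validate_dna(seq: str) -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)!r}")


def _stem_ok(seq: str, i: int, j: int, n: int, max_gu: int | None = None) -> bool:
    """All n pairs (i+k, j-k) Watson-Crick or G.U (at most ``max_gu`` wobble)."""
    gu = 0
    for k in range(n):
        pair = (seq[i + k], seq[j - k])
        if pair not in _PAIRS:
            return False
        if pair in _GU:
            gu += 1
    return max_gu is None or gu <= max_gu


def _stem_gu(seq: str, i: int, j: int, n: int) -> int:
    return sum(1 for k in range(n) if (seq[i + k], seq[j - k]) in _GU)


def _var_arm(seq: str, u: int, v: int, w: ArmWindows) -> bool:
    """Variable region is an arm: long enough and holds a perfect
    internal stem of at least ``var_arm_min_stem`` bp (loop >= 3)."""
    if v < w.var_arm_min_nt:
        return False
    n = w.var_arm_min_stem
    for x in range(u, u + v - (2 * n + 3) + 1):
        for y in range(x + 2 * n + 2, u + v):
            if _stem_ok(seq, x, y, n, w.max_gu_per_stem):
                return True
    return False


def fold_cloverleaf(seq: str, windows: ArmWindows = DEFAULT_WINDOWS
                    ) -> tuple[ArmLayout, int, int] | None:
    """Best full-length cloverleaf decomposition of ``seq``.

    Exhaustive over all arm-length windows; every stem must be fully
    paired (WC or G.U).  Returns (layout, pair_score, gu_pairs) for the
    layout maximizing pair_score — ties broken toward fewer wobble
    pairs, then first in enumeration order — or None when no layout
    satisfies all windows.  Input must be 60-120 nt (DNA or RNA; U is
    read as T).
    """
    seq = seq.upper().replace("U", "T")
    _validate_dna(seq)
    L = len(seq)
    if not windows.length[0] <= L <= windows.length[1]:
        raise ValueError(f"sequence length {L} outside {windows.length}")
    w = windows
    best: tuple[int, int, ArmLayout] | None = None  # (-score_bp, gu, layout)
    cap = w.max_gu_per_stem
    for a in range(w.acceptor[0], w.acceptor[1] + 1):
        if not _stem_ok(seq, 0, L - 1, a, cap):
            continue
        gu_a = _stem_gu(seq, 0, L - 1, a)
        for s1 in range(w.spacer[0], w.spacer[1] + 1):
            q = a + s1
            for d in range(w.d_stem[0], w.d_stem[1] + 1):
                for dl in range(w.d_loop[0], w.d_loop[1] + 1):
                    j_d = q + 2 * d + dl - 1
                    if j_d + 1 > L - a or not _stem_ok(seq, q, j_d, d, cap):
                        continue
                    gu_d = _stem_gu(seq, q, j_d, d)
                    r = q + 2 * d + dl
                    for c in range(w.ac_stem[0], w.ac_stem[1] + 1):
                        j_c = r + 2 * c + w.ac_loop - 1
                        if j_c + 1 > L - a or not _stem_ok(seq, r, j_c, c, cap):
                            continue
                        gu_c = _stem_gu(seq, r, j_c, c)
                        u = j_c + 1
                        rem = (L - a) - u  # var + T arm
                        for t in range(w.t_stem[0], w.t_stem[1] + 1):
                            for tl in range(w.t_loop[0], w.t_loop[1] + 1):
                                v = rem - 2 * t - tl
                                if not w.var[0] <= v <= w.var[1]:
                                    continue
                                x = u + v
                                if not _stem_ok(seq, x, x + 2 * t + tl - 1, t, cap):
                                    continue
                                score_bp = a + d + c + t
                                gu = (gu_a + gu_d + gu_c
                                      + _stem_gu(seq, x, x + 2 * t + tl - 1, t))
                                if best is None or (-score_bp, gu) < best[:2]:
                                    layout = ArmLayout(
                                        acceptor_bp=a, spacer_nt=s1,
                                        d_stem_bp=d, d_loop_nt=dl,
                                        ac_stem_bp=c, ac_loop_nt=w.ac_loop,
                                        var_nt=v, var_is_arm=False,
                                        t_stem_bp=t, t_loop_nt=tl)
                                    best = (-score_bp, gu, layout)
    if best is None:
        return None
    neg_bp, gu, layout = best
    u = (layout.acceptor_bp + layout.spacer_nt + 2 * layout.d_stem_bp
         + layout.d_loop_nt + 2 * layout.ac_stem_bp + layout.ac_loop_nt)
    layout = replace(layout, var_is_arm=_var_arm(seq, u, layout.var_nt, w))
    return layout, -2 * neg_bp, gu


def anticodon_of(seq: str, layout: ArmLayout) -> str:
    """Anticodon (RNA) at positions 3-5 of the 7-nt anticodon loop."""
    seq = seq.upper().replace("U", "T")
    r = (layout.acceptor_bp + layout.spacer_nt
         + 2 * layout.d_stem_bp + layout.d_loop_nt)
    loop_start = r + layout.ac_stem_bp
    return seq[loop_start + 2 : loop_start + 5].replace("T", "U")


def classify_trna(cand: TRNACandidate) -> str:
    """Classify a folded candidate as pyl / sec / standard / ambiguous.

    pyl: CUA anticodon plus a Pyl structural hallmark (6-bp anticodon
    stem or 1-nt acceptor-to-D spacer); sec: UCA anticodon plus a
    variable arm; a reassigned anticodon without its hallmark is
    ambiguous; anything else is standard.
    """
    layout = cand.arm_layout
    if cand.anticodon == "CUA":
        if layout.ac_stem_bp == 6 or layout.spacer_nt == 1:
            return "pyl"
        return "ambiguous"
    if cand.anticodon == "UCA":
        if layout.var_is_arm:
            return "sec"
        return "ambiguous"
    return "standard"


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def _pair_runs(code: np.ndarray, gmax: int) -> tuple[np.ndarray, np.ndarray]:
    """R[x, g] = length of the perfect stem starting at pair (x, x+g)
    and growing inward ((x+1, x+g-1), ...); CG[x, g] = G.U pairs
    cumulated inward along the same anti-diagonal."""
    L = len(code)
    R = np.zeros((L + 2, gmax + 1), dtype=np.int16)
    CG = np.zeros((L + 2, gmax + 1), dtype=np.int16)
    for g in range(gmax + 1):
        m = L - g
        if m <= 0:
            break
        p = _PAIRABLE[code[:m], code[g:]]
        gu = _GU_TABLE[code[:m], code[g:]]
        if g >= 2:
            R[:m, g] = p * (1 + R[1 : m + 1, g - 2])
            CG[:m, g] = gu + CG[1 : m + 1, g - 2]
        else:
            R[:m, g] = p
            CG[:m, g] = gu
    return R, CG


def _shift(arr: np.ndarray, k: int) -> np.ndarray:
    out = np.full(arr.shape, _NEG, dtype=np.int32)
    if k < len(arr):
        out[: len(arr) - k] = arr[k:]
    return out


def _stem_feasible(R: np.ndarray, CG: np.ndarray, gap: int, n: int, L: int,
                   max_gu: int) -> np.ndarray:
    """Bool array over positions: an n-bp perfect stem (within the wobble
    cap) whose outer pair spans ``gap`` exists at this position."""
    val = np.zeros(L + 1, dtype=bool)
    m = L - gap
    if m > 0 and gap < R.shape[1]:
        gu = CG[:m, gap] - CG[n : n + m, gap - 2 * n]
        val[:m] = (R[:m, gap] >= n) & (gu <= max_gu)
    return val


def _best_layout_scores(code: np.ndarray, w: ArmWindows) -> np.ndarray:
    """Max cloverleaf stem pairing (bp) over all legal layouts anchored
    at each position; _NEG where no layout fits.  Exactly equivalent to
    running :func:`fold_cloverleaf` at every (position, total length)."""
    L = len(code)
    gmax = w.length[1]
    R, CG = _pair_runs(code, gmax)
    cap = w.max_gu_per_stem

    # T arm: span = 2t + tl
    t_spans = range(2 * w.t_stem[0] + w.t_loop[0], 2 * w.t_stem[1] + w.t_loop[1] + 1)
    TA: dict[int, np.ndarray] = {}
    for s in t_spans:
        acc = np.full(L + 1, _NEG, dtype=np.int32)
        for t in range(w.t_stem[0], w.t_stem[1] + 1):
            tl = s - 2 * t
            if w.t_loop[0] <= tl <= w.t_loop[1]:
                val = _stem_feasible(R, CG, s - 1, t, L, cap)
                acc[val] = np.maximum(acc[val], t)
        TA[s] = acc

    # variable region + T arm
    VT: dict[int, np.ndarray] = {}
    for sv in range(w.var[0] + min(t_spans), w.var[1] + max(t_spans) + 1):
        acc = np.full(L + 1, _NEG, dtype=np.int32)
        for v in range(w.var[0], w.var[1] + 1):
            s = sv - v
            if s in TA:
                acc = np.maximum(acc, _shift(TA[s], v))
        VT[sv] = acc

    # anticodon arm + var + T
    ACVT: dict[int, np.ndarray] = {}
    ac_spans = [2 * c + w.ac_loop for c in range(w.ac_stem[0], w.ac_stem[1] + 1)]
    for sp in range(min(ac_spans) + min(VT), max(ac_spans) + max(VT) + 1):
        acc = np.full(L + 1, _NEG, dtype=np.int32)
        for c in range(w.ac_stem[0], w.ac_stem[1] + 1):
            inner = sp - (2 * c + w.ac_loop)
            if inner in VT:
                val = _stem_feasible(R, CG, 2 * c + w.ac_loop - 1, c, L, cap)
                cand = np.where(val, c + _shift(VT[inner], 2 * c + w.ac_loop), _NEG)
                acc = np.maximum(acc, cand)
        ACVT[sp] = acc
    del VT, TA

    # D arm feasibility
    DA: dict[int, np.ndarray] = {}
    for sd in range(2 * w.d_stem[0] + w.d_loop[0], 2 * w.d_stem[1] + w.d_loop[1] + 1):
        acc = np.full(L + 1, _NEG, dtype=np.int32)
        for d in range(w.d_stem[0], w.d_stem[1] + 1):
            dl = sd - 2 * d
            if w.d_loop[0] <= dl <= w.d_loop[1]:
                val = _stem_feasible(R, CG, sd - 1, d, L, cap)
                acc[val] = np.maximum(acc[val], d)
        DA[sd] = acc

    # D arm + AC arm + var + T arm
    DACVT: dict[int, np.ndarray] = {}
    for sdv in range(min(DA) + min(ACVT), max(DA) + max(ACVT) + 1):
        acc = np.full(L + 1, _NEG, dtype=np.int32)
        for sd in DA:
            sp = sdv - sd
            if sp in ACVT:
                acc = np.maximum(acc, DA[sd] + _shift(ACVT[sp], sd))
        DACVT[sdv] = acc
    del ACVT, DA

    best = np.full(L + 1, _NEG, dtype=np.int32)
    for a in range(w.acceptor[0], w.acceptor[1] + 1):
        for s1 in range(w.spacer[0], w.spacer[1] + 1):
            for sdv in DACVT:
                total = 2 * a + s1 + sdv
                if not w.length[0] <= total <= w.length[1]:
                    continue
                val = _stem_feasible(R, CG, total - 1, a, L, cap)
                cand = np.where(val, a + _shift(DACVT[sdv], a + s1), _NEG)
                best = np.maximum(best, cand)
    return best[:L]


def _refine_site(oriented: str, p: int, w: ArmWindows
                 ) -> tuple[ArmLayout, int, int] | None:
    """Best full fold over all admissible total lengths starting at p."""
    best = None
    lo, hi = w.length
    for total in range(lo, min(hi, len(oriented) - p) + 1):
        res = fold_cloverleaf(oriented[p : p + total], w)
        if res is None:
            continue
        layout, score, gu = res
        if best is None or (-score, gu) < (-best[1], best[2]):
            best = (layout, score, gu)
    return best


def scan_genome_trnas(contigs: Iterable[Contig],
                      score_threshold: int = SCORE_THRESHOLD,
                      windows: ArmWindows = DEFAULT_WINDOWS) -> list[TRNACandidate]:
    """Scan both strands for cloverleaf folds above ``score_threshold``.

    Candidates are reported greedily by descending pair_score (ties:
    fewer wobble pairs, then leftmost), never overlapping another
    reported candidate on the same strand.
    """
    raw: list[TRNACandidate] = []
    for contig in contigs:
        L = len(contig.seq)
        for strand, oriented in (("+", contig.seq),
                                 ("-", reverse_complement(contig.seq))):
            code = np.array([_CODE[ch] for ch in oriented], dtype=np.int8)
            best = _best_layout_scores(code, windows)
            thr_bp = (score_threshold + 1) // 2
            for p in np.nonzero(best >= thr_bp)[0]:
                res = _refine_site(oriented, int(p), windows)
                if res is None:
                    continue
                layout, score, gu = res
                if score < score_threshold:
                    continue
                total = layout.total_nt
                if strand == "+":
                    start, end = int(p) + 1, int(p) + total
                else:
                    start, end = L - (int(p) + total - 1), L - int(p)
                cand = TRNACandidate(
                    contig_id=contig.id, start=start, end=end, strand=strand,
                    anticodon=anticodon_of(oriented[p : p + total], layout),
                    arm_layout=layout, pair_score=score, gu_pairs=gu)
                raw.append(replace(cand, trna_class=classify_trna(cand)))

    raw.sort(key=lambda c: (-c.pair_score, c.gu_pairs, c.contig_id, c.start))
    chosen: list[TRNACandidate] = []
    for cand in raw:
        clash = any(
            s.contig_id == cand.contig_id and s.strand == cand.strand
            and not (cand.end < s.start or cand.start > s.end)
            for s in chosen)
        if not clash:
            chosen.append(cand)
    chosen.sort(key=lambda c: (c.contig_id, c.start))
    return chosen
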