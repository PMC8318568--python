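"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the expected answer with the most literal
enumeration possible and shares no code path with the implementation
it checks.
"""

from __future__ import annotations

from collections import Counter

from gcescan.align import GAP_EXTEND, GAP_OPEN, _MATRIX
from gcescan.seqcore import reverse_complement

START_CODONS = ("ATG", "GTG", "TTG")
_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "T"), ("T", "G")}


def orf_oracle(seq: str, table, min_len_codons: int, max_readthrough: int
               ) -> set[tuple[int, int, str]]:
    """Six-frame start->stop span enumeration, reduced to the longest
    span per terminal stop; returns {(start, end, strand)} 1-based."""
    out: set[tuple[int, int, str]] = set()
    L = len(seq)
    for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            codons = [oriented[i : i + 3]
                      for i in range(frame, len(oriented) - 2, 3)]
            starts = [k for k, c in enumerate(codons) if c in START_CODONS]
            hard = [k for k, c in enumerate(codons)
                    if table.base_map[c] == "*" and c not in table.readthrough]
            rt = [k for k, c in enumerate(codons) if c in table.readthrough]
            for e in hard:
                prev = max([h for h in hard if h < e], default=-1)
                qualifying = [
                    s for s in starts
                    if prev < s < e
                    and sum(1 for r in rt if s < r < e) <= max_readthrough
                    and (e - s) >= min_len_codons]
                if not qualifying:
                    continue
                s = min(qualifying)
                o_start = frame + 3 * s
                o_end = frame + 3 * e + 2
                if strand == "+":
                    out.add((o_start + 1, o_end + 1, "+"))
                else:
                    out.add((L - o_end, L - o_start, "-"))
    return out


def align_score_oracle(a: str, b: str) -> float:
    """Quadratic-space three-matrix affine-gap global alignment score."""
    neg = float("-inf")
    open_cost = GAP_OPEN + GAP_EXTEND  # charged on the first gap position
    ext = GAP_EXTEND
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(open_cost + (i - 1) * ext)
    for j in range(1, m + 1):
        Y[0][j] = -(open_cost + (j - 1) * ext)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(_MATRIX[a[i - 1], b[j - 1]])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - ext,
                          Y[i - 1][j] - open_cost)
            Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - ext,
                          X[i][j - 1] - open_cost)
    return max(M[n][m], X[n][m], Y[n][m])


def hairpin_oracle(seq: str, min_stem: int, loop_range: tuple[int, int],
                   max_mismatch: int, max_start: int | None = None):
    """All-placements scan; returns (score, start, stem, loop, wc, gu, mm)
    of the best placement under the same tie-breaking, or None."""
    best = None
    L = len(seq)
    for i in range(L):
        if max_start is not None and i > max_start:
            break
        for n in range(min_stem, (L - loop_range[0]) // 2 + 1):
            for loop in range(loop_range[0], loop_range[1] + 1):
                j = i + 2 * n + loop - 1
                if j >= L:
                    continue
                wc = gu = mm = 0
                for k in range(n):
                    pair = (seq[i + k], seq[j - k])
                    if pair in _WC:
                        wc += 1
                    elif pair in _GU:
                        gu += 1
                    else:
                        mm += 1
                if mm > max_mismatch:
                    continue
                score = 2 * wc + gu - 2 * mm
                key = (-score, i, -n, loop)
                if best is None or key < best[0]:
                    best = (key, (score, i, n, loop, wc, gu, mm))
    return None if best is None else best[1]


def consensus_oracle(rows: list[str], threshold: float) -> str:
    """Column-by-column counting with explicit loops."""
    out = []
    for col in range(len(rows[0])):
        letters = [r[col] for r in rows if r[col] != "-"]
        if not letters:
            out.append("-")
            continue
        counts = Counter(letters)
        top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        out.append(top[0] if top[1] > threshold * len(letters) else "X")
    return "".join(out)


def conserved_oracle(rows: list[str], threshold: float) -> list[int]:
    cols = []
    for col in range(len(rows[0])):
        letters = [r[col] for r in rows if r[col] != "-"]
        if letters and max(Counter(letters).values()) > threshold * len(letters):
            cols.append(col + 1)
    return cols
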