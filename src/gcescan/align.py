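"""Global protein alignment with an O/U-extended substitution scheme.

Proteins from amber/opal readthrough carry pyrrolysine (O) and
selenocysteine (U), which no stock substitution matrix covers.  The
scheme here extends BLOSUM62: O-O and U-U score as the matrix's maximum
diagonal value (11), O-K and U-C at half that (pyrrolysine is a lysine
derivative, selenocysteine the selenium analog of cysteine), every other
O/U pairing as a strong mismatch, and X scores 0 against everything.
Alignment itself is delegated to Biopython's PairwiseAligner (global
mode, affine gaps: open 10, extend 1); scores are therefore exactly the
optimum of the usual affine-gap dynamic program.

Percent identity is matches over residue-to-residue columns times 100,
so gap columns (including terminal overhangs) never dilute it.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "global_align",
    "build_substitution_matrix",
    "GAP_OPEN",
    "GAP_EXTEND",
]

#: Affine gap model: a gap of length k costs GAP_OPEN + k * GAP_EXTEND.
GAP_OPEN = 10.0
GAP_EXTEND = 1.0

_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZXOU"
_MISMATCH_OU = -4.0  # most negative BLOSUM62 entry


def build_substitution_matrix() -> substitution_matrices.Array:
    """BLOSUM62 extended with O and U (see module docstring)."""
    blosum = substitution_matrices.load("BLOSUM62")
    mat = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    max_diag = max(float(blosum[a, a]) for a in "ARNDCQEGHILKMFPSTWYV")
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a in "OU" or b in "OU":
                score = _MISMATCH_OU
                if (a, b) in (("O", "O"), ("U", "U")):
                    score = max_diag
                elif {a, b} == {"O", "K"} or {a, b} == {"U", "C"}:
                    score = max_diag / 2.0
                elif "X" in (a, b):
                    score = 0.0
                mat[a, b] = score
            elif "X" in (a, b):
                mat[a, b] = 0.0
            else:
                mat[a, b] = float(blosum[a, b])
    return mat


_MATRIX = build_substitution_matrix()


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _MATRIX
    # Biopython charges open+extend on the first gap position.
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise global alignment.

    ``aligned_a``/``aligned_b`` are gapped strings of equal length;
    removing the gaps recovers the inputs.  ``percent_identity`` is
    matches over residue-to-residue columns.
    """

    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Identity over residue-to-residue columns, x100.

    Columns where either row is a gap (which includes terminal-gap
    overhangs and both-gap columns) do not enter the denominator, so a
    single internal indel between otherwise identical sequences leaves
    the identity at 100.
    """
    cols = 0
    matches = 0
    for a, b in zip(aligned_a, aligned_b):
        if a == "-" or b == "-":
            continue
        cols += 1
        if a == b:
            matches += 1
    if cols == 0:
        return 0.0
    return 100.0 * matches / cols


def coverage_of_shorter(aligned_a: str, aligned_b: str) -> float:
    """Fraction of the shorter sequence sitting in both-residue columns."""
    both = sum(1 for a, b in zip(aligned_a, aligned_b) if a != "-" and b != "-")
    len_a = sum(1 for a in aligned_a if a != "-")
    len_b = sum(1 for b in aligned_b if b != "-")
    shorter = min(len_a, len_b)
    return both / shorter if shorter else 0.0


def global_align(a: str, b: str) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Inputs are non-empty strings over the 20 canonical letters plus
    O, U and X.  Ties between equally optimal alignments are broken
    deterministically (the aligner's first reported alignment).
    """
    for name, seq in (("a", a), ("b", b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq) - set(_ALPHABET)
        if bad:
            raise ValueError(f"sequence {name}: invalid residues {sorted(bad)!r}")
    alignments = _ALIGNER.align(a, b)
    best = alignments[0]
    aligned_a, aligned_b = str(best[0]), str(best[1])
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(best.score),
        percent_identity=percent_identity(aligned_a, aligned_b),
    )
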