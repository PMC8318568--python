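"""Integrate ORF, tRNA and SECIS evidence into recoding calls.

Selenoprotein calls require both an in-frame UGA translated as U and a
passing SECIS hairpin downstream; Pyl-protein verification aligns an
amber-readthrough candidate against a reference methylamine
methyltransferase and asks whether the pyrrolysine columns coincide and
whether the residues following the Pyl site are conserved.  Alignment
house-keeping used throughout the study — consensus sequences with a
strict agreement threshold, conserved-column extraction, greedy
identity-based dereplication — lives here as well.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import AlignmentResult, coverage_of_shorter, global_align
from .io import ReferenceProtein
from .secis import SECISHit
from .seqcore import GeneCall, PYRROLYSINE, SELENOCYSTEINE

__all__ = [
    "PylSiteReport",
    "SelenoproteinCall",
    "verify_pyl_site",
    "call_selenoproteins",
    "consensus_sequence",
    "conserved_columns",
    "dereplicate",
]


@dataclass(frozen=True)
class PylSiteReport:
    """Result of aligning a Pyl candidate against a Pyl reference.

    Positions are 1-based; ``site_aligned`` is true when a candidate O
    column pairs with a reference O column in the global alignment.
    ``downstream_window_identity`` is the percent identity over the
    ``window`` residues following the candidate's Pyl site.
    """

    candidate_id: str
    reference_id: str
    candidate_pyl_pos: int
    candidate_length: int
    reference_pyl_pos: int
    reference_length: int
    site_aligned: bool
    downstream_window_identity: float
    alignment: AlignmentResult = field(repr=False)


@dataclass(frozen=True)
class SelenoproteinCall:
    """A gene with a U event supported by at least one SECIS hit."""

    gene_id: str
    secis_hits: tuple[SECISHit, ...]
    group: str  # "known_family" | "novel"
    family_label: str = ""
    best_reference_identity: float = 0.0
    best_reference_id: str = ""


def verify_pyl_site(candidate: str, reference: str, window: int = 20,
                    candidate_id: str = "candidate",
                    reference_id: str = "reference") -> PylSiteReport:
    """Align a Pyl candidate to a Pyl reference and inspect the O site.

    Both sequences must contain the letter O.  The report carries the
    1-based position and length on each side (e.g. 327 of 485 against
    334 of 483), whether the O columns coincide in the alignment, and
    the identity over the ``window`` residues following the candidate's
    O site (gap-in-candidate columns are skipped; the denominator is
    the full window, so candidates truncated right after the site score
    low).
    """
    if PYRROLYSINE not in candidate:
        raise ValueError("candidate contains no pyrrolysine (O) residue")
    if PYRROLYSINE not in reference:
        raise ValueError("reference contains no pyrrolysine (O) residue")
    if window < 1:
        raise ValueError("window must be >= 1")
    result = global_align(candidate, reference)
    a, b = result.aligned_a, result.aligned_b

    site_aligned = any(x == PYRROLYSINE and y == PYRROLYSINE for x, y in zip(a, b))

    # column of the candidate's first O
    cand_first = candidate.index(PYRROLYSINE)
    seen = -1
    o_col = -1
    for col, x in enumerate(a):
        if x != "-":
            seen += 1
            if seen == cand_first:
                o_col = col
                break
    # if a both-O column exists, anchor the window after it instead
    if site_aligned:
        for col, (x, y) in enumerate(zip(a, b)):
            if x == PYRROLYSINE and y == PYRROLYSINE:
                o_col = col
                break

    consumed = 0
    matches = 0
    for col in range(o_col + 1, len(a)):
        if consumed >= window:
            break
        if a[col] == "-":
            continue
        consumed += 1
        if a[col] == b[col] and b[col] != "-":
            matches += 1
    # denominator is the full window: residues missing after the site
    # cannot be conserved, so a short tail is evidence against the call
    downstream = 100.0 * matches / window

    return PylSiteReport(
        candidate_id=candidate_id,
        reference_id=reference_id,
        candidate_pyl_pos=cand_first + 1,
        candidate_length=len(candidate),
        reference_pyl_pos=reference.index(PYRROLYSINE) + 1,
        reference_length=len(reference),
        site_aligned=site_aligned,
        downstream_window_identity=downstream,
        alignment=result,
    )


def call_selenoproteins(genes: Sequence[GeneCall],
                        secis_hits: Sequence[SECISHit],
                        references: Sequence[ReferenceProtein] = (),
                        min_identity: float = 50.0,
                        min_coverage: float = 0.5) -> list[SelenoproteinCall]:
    """Emit a selenoprotein call per gene with a U event and a SECIS hit.

    A call is ``known_family`` when its best reference alignment reaches
    ``min_identity`` percent identity with ``min_coverage`` of the
    shorter sequence aligned (the family label is taken from that
    reference); otherwise it is ``novel``.  Genes whose U events have no
    passing SECIS hit are absent from the output.
    """
    hits_by_gene: dict[str, list[SECISHit]] = {}
    for hit in secis_hits:
        hits_by_gene.setdefault(hit.gene_id, []).append(hit)

    calls = []
    for gene in genes:
        if not gene.events_with_letter(SELENOCYSTEINE):
            continue
        hits = hits_by_gene.get(gene.gene_id)
        if not hits:
            continue
        best_identity = 0.0
        best_label = ""
        best_ref = ""
        for ref in references:
            result = global_align(gene.protein, ref.seq)
            cov = coverage_of_shorter(result.aligned_a, result.aligned_b)
            if (result.percent_identity >= min_identity and cov >= min_coverage
                    and result.percent_identity > best_identity):
                best_identity = result.percent_identity
                best_label = ref.label or ref.id
                best_ref = ref.id
        group = "known_family" if best_ref else "novel"
        calls.append(SelenoproteinCall(
            gene_id=gene.gene_id,
            secis_hits=tuple(sorted(hits, key=lambda h: h.uga_protein_pos)),
            group=group, family_label=best_label,
            best_reference_identity=best_identity, best_reference_id=best_ref))
    return calls


def _check_rows(alignment: Sequence[str]) -> int:
    if not alignment:
        raise ValueError("alignment has no rows")
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("alignment rows have unequal lengths")
    return width


def consensus_sequence(alignment: Sequence[str], threshold: float = 0.5) -> str:
    """Majority consensus of a gapped protein alignment.

    Per column, the letter whose frequency among non-gap letters
    *strictly* exceeds ``threshold`` is emitted; below that, ``X``
    (positions with insufficient agreement); all-gap columns emit ``-``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    width = _check_rows(alignment)
    out = []
    for col in range(width):
        letters = [row[col] for row in alignment if row[col] != "-"]
        if not letters:
            out.append("-")
            continue
        counts = Counter(letters)
        # deterministic: most frequent, ties broken alphabetically
        letter, count = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out.append(letter if count / len(letters) > threshold else "X")
    return "".join(out)


def conserved_columns(alignment: Sequence[str], threshold: float = 0.75) -> list[int]:
    """1-based indices of columns where one letter's frequency among
    non-gap letters strictly exceeds ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    width = _check_rows(alignment)
    out = []
    for col in range(width):
        letters = [row[col] for row in alignment if row[col] != "-"]
        if not letters:
            continue
        _, count = min(Counter(letters).items(), key=lambda kv: (-kv[1], kv[0]))
        if count / len(letters) > threshold:
            out.append(col + 1)
    return out


def dereplicate(seqs: Mapping[str, str],
                identity_threshold: float = 0.9) -> tuple[list[str], dict[str, str]]:
    """Greedy representative clustering at a global identity threshold.

    Sequences are visited by descending length (ties by id); each joins
    the first existing representative whose global percent identity
    reaches ``identity_threshold * 100``, else founds a new cluster.
    Returns (representative ids, member id -> representative id).
    """
    if not seqs:
        raise ValueError("no sequences to dereplicate")
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    reps: list[str] = []
    membership: dict[str, str] = {}
    for name in order:
        seq = seqs[name]
        for rep in reps:
            if global_align(seq, seqs[rep]).percent_identity >= 100.0 * identity_threshold:
                membership[name] = rep
                break
        else:
            reps.append(name)
            membership[name] = name
    return reps, membership
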