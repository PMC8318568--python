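"""Fragment-based ANI and reciprocal-best-hit AAI between genomes.

ANI follows the Goris-style convention implemented by the commonly used
web calculators: the query genome is chopped into consecutive 1020-nt
fragments, each fragment's best match in the subject is found (exact
k-mer seeding plus edlib infix alignment; an exhaustive mode aligns
against whole contigs), and a fragment counts when it aligns at >= 70%
identity over >= 70% of its length.  A direction's value is the mean
identity of its used fragments; the two-way value is the mean of the
two directions weighted by their fragment counts.

AAI takes best hits in both directions by global protein alignment
(>= 30% identity over >= 70% of the shorter sequence to qualify),
keeps reciprocal best hits, and averages their identities.

When no fragment or no RBH qualifies the result is explicitly
undefined (None) — two unrelated random sequences have ~25% nucleotide
identity, which is noise, not an ANI of 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib

from .align import coverage_of_shorter, global_align
from .seqcore import Contig, reverse_complement

__all__ = ["GenomeComparison", "ani", "aai"]

FRAGMENT_NT = 1020
ANI_MIN_IDENTITY = 0.7
ANI_MIN_COVERAGE = 0.7
SEED_K = 15
AAI_MIN_IDENTITY = 30.0
AAI_MIN_COVERAGE = 0.7


@dataclass(frozen=True)
class GenomeComparison:
    """ANI/AAI summary; percent values are None when undefined."""

    ani_percent: float | None = None
    fragments_total: int = 0
    fragments_used: int = 0
    ani_directions: tuple[float | None, float | None] = (None, None)
    aai_percent: float | None = None
    rbh_count: int = 0
    aai_directions: tuple[float | None, float | None] = (None, None)
    one_way_aai: tuple[float | None, float | None] = (None, None)

    def to_dict(self) -> dict:
        return {
            "ani_percent": self.ani_percent,
            "fragments_total": self.fragments_total,
            "fragments_used": self.fragments_used,
            "ani_directions": list(self.ani_directions),
            "aai_percent": self.aai_percent,
            "rbh_count": self.rbh_count,
            "aai_directions": list(self.aai_directions),
            "one_way_aai": list(self.one_way_aai),
        }


def _fragments(contigs: Sequence[Contig], fragment_nt: int) -> list[str]:
    frags = []
    for contig in contigs:
        for i in range(0, len(contig.seq), fragment_nt):
            frag = contig.seq[i : i + fragment_nt]
            if len(frag) >= 100:  # drop tiny contig tails
                frags.append(frag)
    return frags


def _kmer_index(contigs: Sequence[Contig], k: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ci, contig in enumerate(contigs):
        seq = contig.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((ci, i))
    return index


def _identity_vs_region(frag: str, region: str) -> float:
    """Identity of the best infix alignment of frag inside region."""
    if not region:
        return 0.0
    res = edlib.align(frag, region, mode="HW", task="distance")
    dist = res["editDistance"]
    if dist < 0:
        return 0.0
    return 1.0 - dist / len(frag)


def _best_fragment_identity(frag: str, contigs: Sequence[Contig],
                            index: Mapping[str, list[tuple[int, int]]] | None,
                            k: int, exhaustive: bool) -> float:
    best = 0.0
    for query in (frag, reverse_complement(frag)):
        if exhaustive or index is None:
            for contig in contigs:
                best = max(best, _identity_vs_region(query, contig.seq))
            continue
        # vote on (contig, diagonal) bands from exact k-mer seeds
        votes: dict[tuple[int, int], int] = {}
        for i in range(0, len(query) - k + 1):
            for ci, j in index.get(query[i : i + k], ()):
                band = (ci, (j - i) // 100)
                votes[band] = votes.get(band, 0) + 1
        for (ci, band), _ in sorted(votes.items(), key=lambda kv: -kv[1])[:5]:
            diag_lo = band * 100
            lo = max(0, diag_lo - 60)
            hi = diag_lo + 100 + len(query) + 60
            best = max(best, _identity_vs_region(query, contigs[ci].seq[lo:hi]))
    return best


def ani(genome_a: Sequence[Contig], genome_b: Sequence[Contig],
        fragment_nt: int = FRAGMENT_NT,
        min_identity: float = ANI_MIN_IDENTITY,
        min_coverage: float = ANI_MIN_COVERAGE,
        k: int = SEED_K, exhaustive: bool = False) -> GenomeComparison:
    """Two-way fragment-based average nucleotide identity.

    ``exhaustive=True`` replaces the seeded band search with full infix
    alignment against every contig (exact; for small inputs/testing).
    ``min_coverage`` is the minimum aligned fraction of a fragment; the
    infix alignment always covers the full fragment, so it applies to
    undersized contig tails.
    """
    if not genome_a or not genome_b:
        raise ValueError("both genomes must be non-empty")
    directions = []
    used_counts = []
    totals = []
    for qry, sbj in ((genome_a, genome_b), (genome_b, genome_a)):
        index = None if exhaustive else _kmer_index(sbj, k)
        frags = _fragments(qry, fragment_nt)
        identities = []
        for frag in frags:
            if len(frag) < min_coverage * fragment_nt:
                continue
            ident = _best_fragment_identity(frag, sbj, index, k, exhaustive)
            if ident >= min_identity:
                identities.append(ident)
        totals.append(len(frags))
        used_counts.append(len(identities))
        directions.append(
            100.0 * sum(identities) / len(identities) if identities else None)
    n_a, n_b = used_counts
    if n_a + n_b:
        weighted = ((directions[0] or 0.0) * n_a + (directions[1] or 0.0) * n_b) / (n_a + n_b)
    else:
        weighted = None
    return GenomeComparison(
        ani_percent=weighted, fragments_total=sum(totals),
        fragments_used=n_a + n_b, ani_directions=(directions[0], directions[1]))


def _best_hits(qry: Mapping[str, str], sbj: Mapping[str, str],
               min_identity: float, min_coverage: float) -> dict[str, tuple[str, float]]:
    hits: dict[str, tuple[str, float]] = {}
    for qid, qseq in qry.items():
        best: tuple[str, float] | None = None
        for sid, sseq in sbj.items():
            result = global_align(qseq, sseq)
            cov = coverage_of_shorter(result.aligned_a, result.aligned_b)
            if result.percent_identity < min_identity or cov < min_coverage:
                continue
            if best is None or result.percent_identity > best[1]:
                best = (sid, result.percent_identity)
        if best is not None:
            hits[qid] = best
    return hits


def aai(proteome_a: Mapping[str, str], proteome_b: Mapping[str, str],
        min_identity: float = AAI_MIN_IDENTITY,
        min_coverage: float = AAI_MIN_COVERAGE) -> GenomeComparison:
    """Two-way reciprocal-best-hit average amino acid identity.

    Undefined (None) when no reciprocal best hit passes the filters.
    ``one_way_aai`` carries the per-direction qualifying best-hit means;
    ``aai_directions`` the RBH-restricted directional means whose
    hit-weighted mean is the two-way value.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    ab = _best_hits(proteome_a, proteome_b, min_identity, min_coverage)
    ba = _best_hits(proteome_b, proteome_a, min_identity, min_coverage)
    rbh = [(qa, sb, ident) for qa, (sb, ident) in ab.items()
           if ba.get(sb, (None,))[0] == qa]
    one_way = (
        sum(v for _, v in ab.values()) / len(ab) if ab else None,
        sum(v for _, v in ba.values()) / len(ba) if ba else None,
    )
    if rbh:
        mean_ab = sum(ident for _, _, ident in rbh) / len(rbh)
        mean_ba = sum(ba[sb][1] for _, sb, _ in rbh) / len(rbh)
        two_way = (mean_ab * len(rbh) + mean_ba * len(rbh)) / (2 * len(rbh))
    else:
        mean_ab = mean_ba = two_way = None
    return GenomeComparison(
        aai_percent=two_way, rbh_count=len(rbh),
        aai_directions=(mean_ab, mean_ba), one_way_aai=one_way)
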