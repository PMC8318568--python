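"""Sec/Pyl machinery inventory and gene-neighborhood analysis.

Functional annotation (HMM hits against Pfam/TIGRFAM-style families) is
consumed as an input table, never computed here.  The inventory checks a
genome for the components required for co-translational insertion of
selenocysteine (selA Sec synthase, selB Sec-specific elongation factor,
selC Sec-tRNA, selD selenophosphate synthetase) and pyrrolysine (pylB,
pylC, pylD biosynthesis, pylS pyrrolysyl-tRNA synthetase, pylT
Pyl-tRNA).  The two tRNA components are taken from structural tRNA
classification, not from annotation labels.

Neighborhood queries use strict gene-index distance (< radius genes on
the same contig), matching how methyltransferase loci are described:
the cognate corrinoid protein sits fewer than 10 genes from the
Pyl-containing TMA methyltransferase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .trna import TRNACandidate

__all__ = [
    "AnnotationRow",
    "MachineryChecklist",
    "DEFAULT_COMPONENT_MAP",
    "SEC_COMPONENTS",
    "PYL_COMPONENTS",
    "inventory",
    "neighborhood",
    "cluster_conservation",
    "read_annotation_tsv",
    "write_annotation_tsv",
]

logger = logging.getLogger(__name__)

SEC_COMPONENTS = ("selA", "selB", "selC", "selD")
PYL_COMPONENTS = ("pylB", "pylC", "pylD", "pylS", "pylT")

#: Editable default mapping from annotation labels (accessions or free
#: labels) to machinery components.  Covers the Sec and Pyl systems plus
#: the methylamine-utilization neighborhood (methyltransferases, cognate
#: corrinoid protein, ramA activase), the glycine-betaine
#: methyltransferase (a common Pyl-free mis-annotation decoy) and the
#: CysA sulfate/thiosulfate transporter that also imports Se oxyanions.
DEFAULT_COMPONENT_MAP: dict[str, str] = {
    "selA": "selA", "TIGR00474": "selA",
    "selB": "selB", "TIGR00475": "selB",
    "selD": "selD", "TIGR00476": "selD",
    "pylB": "pylB",
    "pylC": "pylC",
    "pylD": "pylD",
    "pylS": "pylS", "pylRS": "pylS",
    "mttB": "tma_methyltransferase", "tma_mtase": "tma_methyltransferase",
    "mtbB": "dma_methyltransferase",
    "mtmB": "mma_methyltransferase",
    "corrinoid": "pyl_corrinoid", "mttC": "pyl_corrinoid",
    "ramA": "ramA",
    "metH": "metH",
    "gbmt": "gb_methyltransferase", "mtgB": "gb_methyltransferase",
    "cysA": "cysA", "TIGR00968": "cysA",
}


@dataclass(frozen=True)
class AnnotationRow:
    """One gene of a functional-annotation table.

    ``gene_index`` orders genes along their contig; ``family_accessions``
    holds family labels (TIGR/Pfam-style accessions or free labels).
    """

    gene_id: str
    contig_id: str
    gene_index: int
    family_accessions: tuple[str, ...] = ()


@dataclass(frozen=True)
class MachineryChecklist:
    """Presence of the Sec and Pyl machinery in one genome."""

    sec_components: dict[str, bool]
    pyl_components: dict[str, bool]
    copy_counts: dict[str, int]
    sec_complete: bool
    pyl_complete: bool

    def missing(self) -> list[str]:
        return ([c for c in SEC_COMPONENTS if not self.sec_components[c]]
                + [c for c in PYL_COMPONENTS if not self.pyl_components[c]])

    def to_dict(self) -> dict:
        return {
            "sec_components": dict(self.sec_components),
            "pyl_components": dict(self.pyl_components),
            "copy_counts": dict(self.copy_counts),
            "sec_complete": self.sec_complete,
            "pyl_complete": self.pyl_complete,
            "missing": self.missing(),
        }


def _validate_rows(rows: Sequence[AnnotationRow]) -> None:
    seen = set()
    last_index: dict[str, int] = {}
    for row in sorted(rows, key=lambda r: (r.contig_id, r.gene_index)):
        if row.gene_id in seen:
            raise ValueError(f"duplicate gene_id {row.gene_id!r}")
        seen.add(row.gene_id)
        prev = last_index.get(row.contig_id)
        if prev is not None and row.gene_index <= prev:
            raise ValueError(
                f"gene_index not strictly increasing on {row.contig_id!r}")
        last_index[row.contig_id] = row.gene_index


def inventory(annotations: Sequence[AnnotationRow],
              trna_classes: Sequence[TRNACandidate] = (),
              component_map: Mapping[str, str] = DEFAULT_COMPONENT_MAP
              ) -> MachineryChecklist:
    """Build the machinery checklist for one genome.

    A protein component is present when any annotation label maps to it
    (unknown labels are logged and ignored); the tRNA components selC
    and pylT come from structural classification of the genome's tRNAs.
    ``copy_counts`` tallies every occurrence of every mapped component.
    """
    if not component_map:
        raise ValueError("component_map must be non-empty")
    _validate_rows(annotations)
    counts: dict[str, int] = {}
    for row in annotations:
        for label in row.family_accessions:
            component = component_map.get(label)
            if component is None:
                logger.debug("unmapped annotation label %r (gene %s)",
                             label, row.gene_id)
                continue
            counts[component] = counts.get(component, 0) + 1
    counts["selC"] = sum(1 for t in trna_classes if t.trna_class == "sec")
    counts["pylT"] = sum(1 for t in trna_classes if t.trna_class == "pyl")

    sec = {c: counts.get(c, 0) > 0 for c in SEC_COMPONENTS}
    pyl = {c: counts.get(c, 0) > 0 for c in PYL_COMPONENTS}
    return MachineryChecklist(
        sec_components=sec, pyl_components=pyl, copy_counts=counts,
        sec_complete=all(sec.values()), pyl_complete=all(pyl.values()))


def neighborhood(annotations: Sequence[AnnotationRow], anchor_gene_id: str,
                 radius_genes: int = 10) -> list[AnnotationRow]:
    """Genes on the anchor's contig with index distance strictly below
    ``radius_genes`` (anchor excluded), sorted by gene_index.

    Never crosses contig boundaries; a contig edge simply yields fewer
    genes.  Raises KeyError for an unknown anchor.
    """
    anchor = next((r for r in annotations if r.gene_id == anchor_gene_id), None)
    if anchor is None:
        raise KeyError(f"anchor gene {anchor_gene_id!r} not found")
    out = [r for r in annotations
           if r.contig_id == anchor.contig_id and r.gene_id != anchor.gene_id
           and abs(r.gene_index - anchor.gene_index) < radius_genes]
    out.sort(key=lambda r: r.gene_index)
    return out


def cluster_conservation(genomes: Mapping[str, Sequence[AnnotationRow]],
                         anchor_component: str,
                         components: Sequence[str],
                         component_map: Mapping[str, str] = DEFAULT_COMPONENT_MAP,
                         radius_genes: int = 10) -> pd.DataFrame:
    """Per-genome presence/order matrix of a gene cluster.

    For each genome the first gene mapping to ``anchor_component`` is
    the anchor; each requested component is scored by its 1-based
    position within the anchor's neighborhood locus (anchor included,
    genes in index order), or 0 when absent.  Genomes lacking the
    anchor get an all-zero row.  The matrix mirrors a presence/absence
    figure of locus conservation across genomes.
    """
    if not genomes:
        raise ValueError("need at least one genome")

    def components_of(row: AnnotationRow) -> set[str]:
        return {component_map[l] for l in row.family_accessions if l in component_map}

    records = {}
    for name, rows in genomes.items():
        anchor = next((r for r in sorted(rows, key=lambda r: (r.contig_id, r.gene_index))
                       if anchor_component in components_of(r)), None)
        if anchor is None:
            records[name] = {c: 0 for c in components}
            continue
        locus = neighborhood(rows, anchor.gene_id, radius_genes) + [anchor]
        locus.sort(key=lambda r: r.gene_index)
        position: dict[str, int] = {}
        for i, row in enumerate(locus, start=1):
            for comp in components_of(row):
                position.setdefault(comp, i)
        records[name] = {c: position.get(c, 0) for c in components}
    return pd.DataFrame.from_dict(records, orient="index", columns=list(components))


def read_annotation_tsv(path: str | Path) -> list[AnnotationRow]:
    """Read an annotation TSV: gene_id, contig_id, gene_index,
    semicolon-joined family accessions."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_id", "contig_id", "gene_index", "family_accessions"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    rows = [
        AnnotationRow(
            gene_id=rec.gene_id, contig_id=rec.contig_id,
            gene_index=int(rec.gene_index),
            family_accessions=tuple(a for a in rec.family_accessions.split(";") if a))
        for rec in df.itertuples()
    ]
    _validate_rows(rows)
    return rows


def write_annotation_tsv(rows: Sequence[AnnotationRow], path: str | Path) -> None:
    df = pd.DataFrame({
        "gene_id": [r.gene_id for r in rows],
        "contig_id": [r.contig_id for r in rows],
        "gene_index": [r.gene_index for r in rows],
        "family_accessions": [";".join(r.family_accessions) for r in rows],
    })
    df.to_csv(path, sep="\t", index=False)
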