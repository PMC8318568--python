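"""Reading and writing the standard formats used by the pipeline.

FASTA goes through Biopython; GFF3 is written/read with a small
column-discipline layer (feature type ``CDS`` for gene calls, attribute
``readthrough=pos:codon:letter`` for recoded stops, ``tRNA`` features for
tRNA genes).  Coordinates are 1-based inclusive throughout, matching GFF3.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import Contig, GeneCall

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_proteins",
    "ReferenceProtein",
    "read_labeled_proteins",
    "write_gff3",
    "read_gff3",
    "Gff3Feature",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYOUX*-BZ")


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a (multi-record, wrapped or unwrapped) DNA FASTA into contigs."""
    contigs = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        contigs.append(Contig(id=rec.id, seq=str(rec.seq).upper()))
    if not contigs:
        raise ValueError(f"{path}: no FASTA records found")
    return contigs


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    """Write sequences (id -> sequence) as wrapped FASTA."""
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_proteins(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA (letters O and U are legal) as id -> sequence."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"{path}:{rec.id}: invalid residues {sorted(bad)!r}")
        if rec.id in out:
            raise ValueError(f"{path}: duplicate protein id {rec.id!r}")
        out[rec.id] = seq
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


@dataclass(frozen=True)
class ReferenceProtein:
    """A labeled reference protein (family label from the description)."""

    id: str
    seq: str
    label: str = ""


def read_labeled_proteins(path: str | Path) -> list[ReferenceProtein]:
    """Read a reference protein FASTA; ``family=...`` in the description
    (or, failing that, the whole description) becomes the family label."""
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = ""
        desc = rec.description[len(rec.id):].strip()
        for token in desc.split():
            if token.startswith("family="):
                label = token[len("family="):]
                break
        else:
            label = desc
        refs.append(ReferenceProtein(id=rec.id, seq=str(rec.seq).upper(), label=label))
    if not refs:
        raise ValueError(f"{path}: no FASTA records found")
    return refs


def write_protein_fasta_records(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _esc(value: str) -> str:
    return urllib.parse.quote(str(value), safe="")


def _unesc(value: str) -> str:
    return urllib.parse.unquote(value)


@dataclass(frozen=True)
class Gff3Feature:
    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str]


def format_gene_gff3_line(gene: GeneCall, source: str = "gcescan") -> str:
    attrs = [("ID", gene.gene_id)]
    if gene.readthrough_events:
        attrs.append(("readthrough", ",".join(
            f"{ev.genomic_pos}:{ev.codon}:{ev.letter}"
            for ev in gene.readthrough_events)))
    attr_str = ";".join(f"{k}={_esc(v)}" for k, v in attrs)
    return "\t".join([gene.contig_id, source, "CDS", str(gene.start),
                      str(gene.end), ".", gene.strand, "0", attr_str])


def write_gff3(genes: Sequence[GeneCall], path: str | Path,
               source: str = "gcescan") -> None:
    """Write gene calls as GFF3 CDS features; readthrough events are kept
    in a ``readthrough=pos:codon:letter[,...]`` attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            fh.write(format_gene_gff3_line(gene, source) + "\n")


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            attrs = {}
            for part in cols[8].split(";"):
                if not part:
                    continue
                key, _, val = part.partition("=")
                attrs[key] = _unesc(val)
            feats.append(Gff3Feature(
                seqid=cols[0], source=cols[1], type=cols[2],
                start=int(cols[3]), end=int(cols[4]), score=cols[5],
                strand=cols[6], phase=cols[7], attributes=attrs))
    return feats


def parse_readthrough_attribute(value: str) -> list[tuple[int, str, str]]:
    """Parse ``pos:codon:letter[,...]`` back into tuples."""
    out = []
    for item in value.split(","):
        pos, codon, letter = item.split(":")
        out.append((int(pos), codon, letter))
    return out
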