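"""Orchestration: genome in, genetic-code-expansion report out.

``run_scan`` chains readthrough-aware gene calling, tRNA folding, SECIS
detection, selenoprotein/Pyl calling and the machinery inventory, and
flags a genome as "dual GCE" when it has the complete Sec *and* Pyl
machinery together with at least one selenoprotein call and one
verified Pyl protein.  ``run_compare`` wraps the ANI/AAI calculators.
All thresholds live in :class:`RunConfig`, which round-trips through
YAML and is embedded in every report for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import compare as compare_mod
from . import secis as secis_mod
from . import trna as trna_mod
from .compare import GenomeComparison, aai, ani
from .io import ReferenceProtein
from .machinery import AnnotationRow, MachineryChecklist, inventory
from .recoding import (PylSiteReport, SelenoproteinCall, call_selenoproteins,
                       verify_pyl_site)
from .secis import SECISHit, scan_secis_genome
from .seqcore import (Contig, GeneCall, TranslationTable, find_orfs_genome,
                      PYRROLYSINE, SELENOCYSTEINE)
from .trna import TRNACandidate, scan_genome_trnas

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ScanResult", "run_scan", "run_compare", "validate_report"]

_MODES = ("standard", "amber", "opal", "dual")


@dataclass
class RunConfig:
    """All stage thresholds of one pipeline run (YAML round-trippable)."""

    mode: str = "dual"
    # ORF calling
    min_len_codons: int = 60
    max_readthrough: int = 2
    # tRNA scan
    trna_score_threshold: int = trna_mod.SCORE_THRESHOLD
    # SECIS scan
    secis_window_nt: int = secis_mod.WINDOW_NT
    secis_min_stem: int = secis_mod.MIN_STEM
    secis_loop_min: int = secis_mod.LOOP_RANGE[0]
    secis_loop_max: int = secis_mod.LOOP_RANGE[1]
    secis_max_mismatch: int = secis_mod.MAX_MISMATCH
    secis_max_offset: int = secis_mod.MAX_OFFSET
    secis_score_threshold: int = secis_mod.SCORE_THRESHOLD
    # selenoprotein grouping
    known_family_min_identity: float = 50.0
    known_family_min_coverage: float = 0.5
    # Pyl verification
    pyl_window: int = 20
    pyl_min_downstream_identity: float = 60.0
    # genome comparison
    ani_fragment_nt: int = compare_mod.FRAGMENT_NT
    ani_min_identity: float = compare_mod.ANI_MIN_IDENTITY
    aai_min_identity: float = compare_mod.AAI_MIN_IDENTITY
    aai_min_coverage: float = compare_mod.AAI_MIN_COVERAGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.min_len_codons < 2:
            raise ValueError("min_len_codons must be >= 2")
        if self.max_readthrough < 0:
            raise ValueError("max_readthrough must be >= 0")
        if not 3 <= self.secis_loop_min <= self.secis_loop_max:
            raise ValueError("invalid SECIS loop range")
        if not 0 < self.ani_min_identity <= 1:
            raise ValueError("ani_min_identity must be in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def table(self) -> TranslationTable:
        return TranslationTable.from_mode(self.mode)


@dataclass
class ScanResult:
    """Everything one ``run_scan`` produced."""

    config: RunConfig
    genes: list[GeneCall]
    trnas: list[TRNACandidate]
    secis_hits: list[SECISHit]
    selenoprotein_calls: list[SelenoproteinCall]
    pyl_reports: list[tuple[str, PylSiteReport]]  # (gene_id, report), verified calls
    checklist: MachineryChecklist | None
    report: dict


def _pyl_calls(genes: Sequence[GeneCall], references: Sequence[ReferenceProtein],
               config: RunConfig) -> list[tuple[str, PylSiteReport]]:
    """Verified Pyl-protein calls: an amber-readthrough gene counts when
    its O column aligns to a reference O column and the residues after
    the site are conserved."""
    pyl_refs = [r for r in references if PYRROLYSINE in r.seq]
    calls = []
    for gene in genes:
        if not gene.events_with_letter(PYRROLYSINE) or not pyl_refs:
            continue
        best: PylSiteReport | None = None
        for ref in pyl_refs:
            report = verify_pyl_site(gene.protein, ref.seq, window=config.pyl_window,
                                     candidate_id=gene.gene_id, reference_id=ref.id)
            if best is None or (report.downstream_window_identity
                                > best.downstream_window_identity):
                best = report
        if (best is not None and best.site_aligned
                and best.downstream_window_identity >= config.pyl_min_downstream_identity):
            calls.append((gene.gene_id, best))
    return calls


def run_scan(contigs: Sequence[Contig], config: RunConfig | None = None,
             references: Sequence[ReferenceProtein] = (),
             annotations: Sequence[AnnotationRow] | None = None) -> ScanResult:
    """Run the full detection pipeline on one genome."""
    config = config or RunConfig()
    table = config.table()
    timer = time.perf_counter()

    genes = find_orfs_genome(contigs, table, config.min_len_codons,
                             config.max_readthrough)
    logger.info("gene calling: %d ORFs (%.1fs)", len(genes),
                time.perf_counter() - timer)

    trnas = scan_genome_trnas(contigs, score_threshold=config.trna_score_threshold)
    logger.info("tRNA scan: %d candidates", len(trnas))

    secis_hits = scan_secis_genome(
        genes, contigs, window_nt=config.secis_window_nt,
        min_stem=config.secis_min_stem,
        loop_range=(config.secis_loop_min, config.secis_loop_max),
        max_mismatch=config.secis_max_mismatch,
        max_offset=config.secis_max_offset,
        score_threshold=config.secis_score_threshold)
    logger.info("SECIS scan: %d hits", len(secis_hits))

    seleno_calls = call_selenoproteins(
        genes, secis_hits, references,
        min_identity=config.known_family_min_identity,
        min_coverage=config.known_family_min_coverage)
    pyl_reports = _pyl_calls(genes, references, config)

    checklist = (inventory(annotations, trnas) if annotations is not None else None)
    dual_gce = bool(
        checklist is not None and checklist.sec_complete and checklist.pyl_complete
        and seleno_calls and pyl_reports)

    trna_class_counts: dict[str, int] = {}
    for t in trnas:
        trna_class_counts[t.trna_class] = trna_class_counts.get(t.trna_class, 0) + 1
    report = {
        "mode": config.mode,
        "n_genes": len(genes),
        "n_genes_with_amber_readthrough": sum(
            1 for g in genes if g.events_with_letter(PYRROLYSINE)),
        "n_genes_with_opal_readthrough": sum(
            1 for g in genes if g.events_with_letter(SELENOCYSTEINE)),
        "selenoproteins": {
            "count": len(seleno_calls),
            "known_family": sum(1 for c in seleno_calls if c.group == "known_family"),
            "novel": sum(1 for c in seleno_calls if c.group == "novel"),
            "calls": [{
                "gene_id": c.gene_id, "group": c.group,
                "family_label": c.family_label,
                "best_reference_identity": round(c.best_reference_identity, 2),
                "uga_positions": [h.uga_protein_pos for h in c.secis_hits],
            } for c in seleno_calls],
        },
        "pyl_proteins": {
            "count": len(pyl_reports),
            "calls": [{
                "gene_id": gid,
                "reference_id": r.reference_id,
                "pyl_position": r.candidate_pyl_pos,
                "protein_length": r.candidate_length,
                "reference_pyl_position": r.reference_pyl_pos,
                "reference_length": r.reference_length,
                "site_aligned": r.site_aligned,
                "downstream_window_identity": round(r.downstream_window_identity, 2),
            } for gid, r in pyl_reports],
        },
        "trnas": {"count": len(trnas), "classes": trna_class_counts},
        "machinery": checklist.to_dict() if checklist is not None else None,
        "dual_gce": dual_gce,
        "config": dataclasses.asdict(config),
    }
    validate_report(report)
    return ScanResult(config=config, genes=genes, trnas=trnas,
                      secis_hits=secis_hits, selenoprotein_calls=seleno_calls,
                      pyl_reports=pyl_reports, checklist=checklist, report=report)


_REPORT_SCHEMA = {
    "mode": str, "n_genes": int, "n_genes_with_amber_readthrough": int,
    "n_genes_with_opal_readthrough": int, "selenoproteins": dict,
    "pyl_proteins": dict, "trnas": dict, "machinery": (dict, type(None)),
    "dual_gce": bool, "config": dict,
}


def validate_report(report: Mapping) -> None:
    """Light schema validation: keys, types, count consistency."""
    for key, typ in _REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has wrong type")
    if report["selenoproteins"]["count"] != len(report["selenoproteins"]["calls"]):
        raise ValueError("selenoprotein count does not match call list")
    if report["pyl_proteins"]["count"] != len(report["pyl_proteins"]["calls"]):
        raise ValueError("pyl count does not match call list")


def run_compare(genome_a: Sequence[Contig] | None = None,
                genome_b: Sequence[Contig] | None = None,
                proteome_a: Mapping[str, str] | None = None,
                proteome_b: Mapping[str, str] | None = None,
                config: RunConfig | None = None,
                exhaustive: bool = False) -> dict:
    """ANI (from genomes) and/or AAI (from proteomes) as a JSON-ready dict.

    Undefined metrics serialize as null, never as 0.
    """
    config = config or RunConfig()
    result = GenomeComparison()
    merged: dict = {}
    if genome_a is not None and genome_b is not None:
        nucl = ani(genome_a, genome_b, fragment_nt=config.ani_fragment_nt,
                   min_identity=config.ani_min_identity, exhaustive=exhaustive)
        merged.update({k: v for k, v in nucl.to_dict().items()
                       if k.startswith(("ani", "fragments"))})
    if proteome_a is not None and proteome_b is not None:
        prot = aai(proteome_a, proteome_b, min_identity=config.aai_min_identity,
                   min_coverage=config.aai_min_coverage)
        merged.update({k: v for k, v in prot.to_dict().items()
                       if k.startswith(("aai", "rbh", "one_way"))})
    if not merged:
        raise ValueError("need two genomes and/or two proteomes")
    return merged


def write_scan_outputs(result: ScanResult, outdir: str | Path) -> dict[str, Path]:
    """Write report.json, features.gff3, proteins.faa and the TSVs."""
    import pandas as pd

    from .io import write_fasta, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": outdir / "report.json",
        "gff3": outdir / "features.gff3",
        "proteins": outdir / "proteins.faa",
        "trna_tsv": outdir / "trna.tsv",
        "secis_tsv": outdir / "secis.tsv",
        "calls_tsv": outdir / "calls.tsv",
    }
    paths["report"].write_text(json.dumps(result.report, indent=1, sort_keys=True))
    write_gff3(result.genes, paths["gff3"])
    write_fasta({g.gene_id: g.protein for g in result.genes}, paths["proteins"])
    pd.DataFrame([{
        "contig": t.contig_id, "start": t.start, "end": t.end, "strand": t.strand,
        "anticodon": t.anticodon, "class": t.trna_class, "pair_score": t.pair_score,
        "acceptor_bp": t.arm_layout.acceptor_bp, "spacer_nt": t.arm_layout.spacer_nt,
        "d_stem_bp": t.arm_layout.d_stem_bp, "d_loop_nt": t.arm_layout.d_loop_nt,
        "ac_stem_bp": t.arm_layout.ac_stem_bp, "var_nt": t.arm_layout.var_nt,
        "var_is_arm": t.arm_layout.var_is_arm, "t_stem_bp": t.arm_layout.t_stem_bp,
        "t_loop_nt": t.arm_layout.t_loop_nt,
    } for t in result.trnas]).to_csv(paths["trna_tsv"], sep="\t", index=False)
    pd.DataFrame([{
        "gene_id": h.gene_id, "uga_protein_pos": h.uga_protein_pos,
        "offset_nt": h.offset_nt, "stem_bp": h.stem_bp, "loop_nt": h.loop_nt,
        "mismatches": h.mismatches, "span_nt": h.span_nt, "score": h.score,
    } for h in result.secis_hits]).to_csv(paths["secis_tsv"], sep="\t", index=False)
    rows = [{
        "call_type": "selenoprotein", "gene_id": c.gene_id, "group": c.group,
        "family_label": c.family_label,
        "best_reference_identity": round(c.best_reference_identity, 2),
        "detail": ";".join(f"U@{h.uga_protein_pos}" for h in c.secis_hits),
    } for c in result.selenoprotein_calls]
    rows += [{
        "call_type": "pyl_protein", "gene_id": gid, "group": "",
        "family_label": r.reference_id,
        "best_reference_identity": round(r.downstream_window_identity, 2),
        "detail": f"O@{r.candidate_pyl_pos}/{r.candidate_length}"
                  f"~ref@{r.reference_pyl_pos}/{r.reference_length}",
    } for gid, r in result.pyl_reports]
    pd.DataFrame(rows).to_csv(paths["calls_tsv"], sep="\t", index=False)
    return paths
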