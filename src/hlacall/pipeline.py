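"""End-to-end orchestration: reference databases -> read classification ->
assembly -> contig matching -> scoring -> designation -> G-group resolution
-> phase ambiguity -> coverage QC -> report."""

from __future__ import annotations

import logging
import statistics
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from . import io as hio
from .assemble import assemble_bin, filter_contigs
from .calling import (
    TypingCall,
    designate_alleles,
    detect_phase_ambiguity,
    match_contigs,
    resolve_minor_exons,
    score_alleles,
)
from .classify import ReadBin, Read, best_supported_allele, classify_reads
from .mapper import MappingParams, PanelIndex
from .qc import QCReport, coverage_profile
from .refdb import (
    AlleleRecord,
    ExactDB,
    build_crp,
    build_exact_dbs,
    parse_allele_set,
    targeted_exons,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA = {
    "required": ["parameters", "classification", "genes"],
    "gene_row_required": [
        "gene",
        "alleles",
        "resolution",
        "homozygous",
        "no_call",
        "phase_ambiguous",
        "qc",
    ],
}


@dataclass
class PipelineConfig:
    """Inputs, outputs and the method's tunable constants.

    Defaults follow the method's stated constants: 50 bp intron flanks on
    the mapping panel and a five-fold mean-depth contig filter.
    """

    allele_set: str | Path = ""
    frequency_table: str | Path | None = None
    fastq: list[str | Path] = field(default_factory=list)
    out_dir: str | Path | None = None
    target_genes: list[str] | None = None
    competitor_genes: list[str] = field(default_factory=list)
    flank_len: int = 50
    min_overlap: int = 20
    min_mean_depth: float = 5.0
    read_length: int | None = None  # inferred from the reads when unset
    mapping: MappingParams = field(default_factory=MappingParams)
    seed: int = 0
    write_contigs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        mapping = data.pop("mapping", None)
        cfg = cls(**data)
        if mapping:
            cfg.mapping = MappingParams(**mapping)
        return cfg


@dataclass
class PipelineResult:
    calls: dict[str, TypingCall]
    report: dict
    stats: object
    contigs: dict[str, list]

    @property
    def any_no_call(self) -> bool:
        return any(c.no_call for c in self.calls.values())


def run_pipeline(
    cfg: PipelineConfig,
    records: Sequence[AlleleRecord] | None = None,
    reads: Iterable[Read] | None = None,
    frequencies: hio.FrequencyTable | None = None,
    panel_index: PanelIndex | None = None,
    dbs: tuple[ExactDB, ExactDB] | None = None,
) -> PipelineResult:
    """Execute the full typing pipeline.

    Inputs may be passed in memory (``records``/``reads``/...) or read from
    the paths in ``cfg``.  ``panel_index`` and ``dbs`` allow reuse of the
    built databases across samples.
    """
    t0 = time.perf_counter()
    if records is None:
        records = parse_allele_set(cfg.allele_set)
    if frequencies is None:
        frequencies = (
            hio.load_frequency_table(cfg.frequency_table)
            if cfg.frequency_table
            else hio.FrequencyTable()
        )
    competitor = set(cfg.competitor_genes)
    targets = (
        set(cfg.target_genes)
        if cfg.target_genes
        else {r.gene for r in records} - competitor
    )
    target_records = [r for r in records if r.gene in targets]
    if dbs is None:
        dbs = build_exact_dbs(target_records)
    mdb, adb = dbs
    if panel_index is None:
        panel = build_crp(records, targets, competitor, cfg.flank_len)
        panel_index = PanelIndex(panel, cfg.mapping)

    if reads is None:
        reads = [r for fq in cfg.fastq for r in hio.read_fastq(fq)]
    else:
        reads = list(reads)
    logger.info("classifying %d reads against %d panel entries",
                len(reads), len(panel_index.entries))
    bins, stats = classify_reads(reads, panel_index, target_genes=targets)

    read_length = cfg.read_length
    if read_length is None:
        read_length = (
            int(statistics.median(len(r.sequence) for r in reads)) if reads else 100
        )

    # A read passes the mapper with up to (1 - min_score_frac)/2 of its
    # length outside the panel window, so contigs may overhang the exon by
    # the flank plus that intrusion; the matcher must tolerate both.
    intrusion = int(read_length * (1.0 - cfg.mapping.min_score_frac) / 2.0)
    match_flank = cfg.flank_len + intrusion

    exons_by_allele = {
        r.label: {e: r.exon(e) for e in targeted_exons(r.gene) if r.exon(e)}
        for r in target_records
    }
    first_allele_by_gene: dict[str, str] = {}
    for r in sorted(target_records, key=lambda r: r.label):
        first_allele_by_gene.setdefault(r.gene, r.label)

    calls: dict[str, TypingCall] = {}
    contigs_by_gene: dict[str, list] = {}
    for gene in sorted(targets):
        bin = bins.get(gene, ReadBin(gene))
        ref_allele = best_supported_allele(stats, gene) or first_allele_by_gene.get(gene)
        qc_report = (
            coverage_profile(bin, exons_by_allele.get(ref_allele, {}))
            if ref_allele
            else QCReport(gene=gene)
        )
        if not bin.reads:
            call = TypingCall(gene=gene, no_call=True, qc=qc_report)
            call.notes.append("no reads classified to this gene")
            calls[gene] = call
            contigs_by_gene[gene] = []
            continue
        contigs = filter_contigs(
            assemble_bin(bin, cfg.min_overlap, seed=cfg.seed), cfg.min_mean_depth
        )
        contigs_by_gene[gene] = contigs
        matches, unmatched_mdb = match_contigs(
            contigs, mdb, gene, cfg.min_overlap, match_flank
        )
        scores = score_alleles(matches)
        call = designate_alleles(scores, matches, frequencies, qc=qc_report)
        call.gene = gene
        call.qc = qc_report
        call = resolve_minor_exons(call, contigs, adb, cfg.min_overlap, match_flank)
        call = detect_phase_ambiguity(call, matches, read_length, mdb, frequencies)
        adb_matches, _ = match_contigs(contigs, adb, gene, cfg.min_overlap, match_flank)
        matched_ids = {m.contig_id for m in matches} | {m.contig_id for m in adb_matches}
        call.novel_contigs = [i for i in unmatched_mdb if i not in matched_ids]
        if call.novel_contigs:
            call.notes.append(
                "high-depth contigs without a database match documented for "
                "novel-allele review"
            )
        calls[gene] = call

    report = build_report(cfg, calls, stats, contigs_by_gene, read_length)
    report["runtime_s"] = round(time.perf_counter() - t0, 2)
    if cfg.out_dir:
        write_outputs(cfg, report, contigs_by_gene)
    return PipelineResult(calls=calls, report=report, stats=stats, contigs=contigs_by_gene)


def build_report(cfg, calls, stats, contigs_by_gene, read_length) -> dict:
    rows = []
    for gene in sorted(calls):
        c = calls[gene]
        qc = c.qc.summary() if isinstance(c.qc, QCReport) else {"tier": "fail"}
        rows.append(
            {
                "gene": gene,
                "alleles": list(c.reported_pair),
                "resolution": list(c.resolution),
                "homozygous": c.homozygous,
                "no_call": c.no_call,
                "phase_ambiguous": c.phase_ambiguous,
                "phase_alternatives": [list(p) for p in c.phase_alternatives],
                "extra_allele_contigs": list(c.extra_allele_contigs),
                "novel_contigs": list(c.novel_contigs),
                "score_trace": [[l, s] for l, s in c.score_trace],
                "n_contigs": len(contigs_by_gene.get(gene, [])),
                "qc": qc,
                "notes": list(c.notes),
            }
        )
    return {
        "parameters": {
            "flank_len": cfg.flank_len,
            "min_overlap": cfg.min_overlap,
            "min_mean_depth": cfg.min_mean_depth,
            "read_length": read_length,
            "seed": cfg.seed,
        },
        "classification": {
            "total": stats.total,
            "binned": stats.binned,
            "ambiguous_excluded": stats.ambiguous_excluded,
            "unmapped": stats.unmapped,
            "competitor_absorbed": stats.competitor_absorbed,
            "per_gene": dict(stats.per_gene),
        },
        "genes": rows,
    }


def validate_report(report: dict) -> None:
    """Check the report against the shipped schema; raises ValueError."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
    for row in report["genes"]:
        for key in REPORT_SCHEMA["gene_row_required"]:
            if key not in row:
                raise ValueError(f"gene row missing key {key!r}")
        if len(row["alleles"]) > 2:
            raise ValueError("more than two reported alleles")


def write_outputs(cfg: PipelineConfig, report: dict, contigs_by_gene) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hio.write_json(report, out / "report.json")
    import pandas as pd

    rows = [
        {
            "gene": r["gene"],
            "alleles": ";".join(r["alleles"]) or "no-call",
            "resolution": ";".join(r["resolution"]),
            "homozygous": r["homozygous"],
            "phase_ambiguous": r["phase_ambiguous"],
            "qc_tier": r["qc"].get("tier"),
            "qc_warning": r["qc"].get("warning"),
            "notes": " | ".join(r["notes"]),
        }
        for r in report["genes"]
    ]
    pd.DataFrame(rows).to_csv(out / "report.tsv", sep="\t", index=False)
    if cfg.write_contigs:
        for gene, contigs in contigs_by_gene.items():
            if contigs:
                hio.write_contig_fasta(contigs, out / f"{gene.replace('*','_')}.contigs.fasta")
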