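"""End-to-end orchestration: load -> count -> TPM -> filter -> intersect ->
enumerate -> assign -> call -> summarize.

The pipeline consumes a genome FASTA, a GTF annotation, ribosome-footprint
alignments (BED6, one file per replicate) and gene-level count tables for
the total and polysomal RNA-seq fractions, and emits the expression table,
the enumerated smORFs, the translation calls, a microprotein FASTA and a
summary JSON that records every threshold, convention choice and per-stage
funnel count. Deterministic given its inputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import GeneModel, load_annotation
from .occupancy import (
    IN_FRAME_DEFINITION,
    TranslationCall,
    assign_footprints,
    call_translated,
    in_frame_summary,
)
from .orfs import SmORF, deduplicate_smorfs, enumerate_smorfs
from .quant import (
    ExpressionTable,
    FilterConfig,
    count_exonic_reads,
    filter_by_length,
    filter_expressed,
    intersect_datasets,
    read_bed6,
)
from .simulate import TruthRecord, read_counts_tsv


@dataclass
class RunConfig:
    fasta: Path
    gtf: Path
    ribo_beds: list[Path]
    total_counts: Path
    poly_counts: Path
    outdir: Path
    filters: FilterConfig = field(default_factory=FilterConfig)
    stranded: bool = False
    require_in_frame: bool = False

    def validate(self) -> None:
        paths = [self.fasta, self.gtf, self.total_counts, self.poly_counts, *self.ribo_beds]
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        if not self.ribo_beds:
            raise ValueError("at least one ribo footprint BED is required")


@dataclass
class PipelineResult:
    genes: list[GeneModel]
    table: ExpressionTable
    passing: dict[str, dict[str, set[str]]]  # role -> class -> gene ids
    common_lncrna: set[str]
    smorfs: list[SmORF]
    calls: list[TranslationCall]
    summary: dict

    @property
    def called(self) -> list[TranslationCall]:
        return [c for c in self.calls if c.called]


def _stage(name: str):  # decorator-free error contextualisation
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class PipelineStageError(RuntimeError):
    """An error raised by a named pipeline stage."""


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    cfg.validate()
    f = cfg.filters
    diagnostics: dict[str, int] = {}
    summary: dict = {
        "version": __version__,
        "thresholds": {
            "min_reads_replicate_average": f.min_reads,
            "tpm_lncRNA": f.tpm_lnc,
            "tpm_protein_coding": f.tpm_coding,
            "min_orf_nt": f.min_orf_nt,
            "min_smorf_reads_exclusive": f.min_smorf_reads_exclusive,
            "read_length_window": [f.min_read_len, f.max_read_len],
            "psite_offset": f.psite_offset,
        },
        "conventions": {
            "orf_nt_length": "stop codon excluded (nt = 3 x aa)",
            "smorf_counting_interval": "[start, stop_end) including the stop codon",
            "footprint_position": "5'-most transcribed base + psite_offset",
            "tpm_length_term": "gene exon-union length",
            "tpm_counts": "pooled over replicates",
            "read_count_criterion": "replicate average",
            "in_frame": IN_FRAME_DEFINITION,
            "isoforms": "smORFs enumerated on all isoforms, deduplicated by "
                        "(gene, peptide)",
        },
        "funnel": {},
        "dropped": diagnostics,
    }

    with _stage("load"):
        genes = load_annotation(cfg.gtf, cfg.fasta)
    summary["funnel"]["genes_annotated"] = len(genes)

    with _stage("count"):
        ribo_reps = []
        n_length_filtered = 0
        for bed in cfg.ribo_beds:
            reads = read_bed6(bed)
            kept = filter_by_length(reads, f.min_read_len, f.max_read_len)
            n_length_filtered += len(reads) - len(kept)
            ribo_reps.append(
                count_exonic_reads(kept, genes, cfg.stranded, diagnostics)
            )
        diagnostics["length_filtered_reads"] = n_length_filtered
        role_counts = {
            "ribo": ribo_reps,
            "total": read_counts_tsv(cfg.total_counts),
            "poly": read_counts_tsv(cfg.poly_counts),
        }

    with _stage("tpm"):
        table = ExpressionTable.from_counts(genes, role_counts)

    with _stage("filter"):
        passing = {role: filter_expressed(table, role, f) for role in role_counts}
    for role, sets in passing.items():
        summary["funnel"][f"lncRNA_expressed_{role}"] = len(sets["lncRNA"])
        summary["funnel"][f"coding_expressed_{role}"] = len(sets["protein_coding"])

    with _stage("intersect"):
        common = intersect_datasets(
            *(passing[role]["lncRNA"] for role in ("ribo", "total", "poly"))
        )
    summary["funnel"]["lncRNA_common"] = len(common)

    gene_by_id = {g.gene_id: g for g in genes}
    with _stage("enumerate"):
        smorfs: list[SmORF] = []
        n_candidates = 0
        for gid in sorted(common):
            for tm in gene_by_id[gid].transcripts:
                found = enumerate_smorfs(tm, f.min_orf_nt)
                n_candidates += len(found)
                smorfs.extend(found)
    summary["funnel"]["smorfs_enumerated"] = n_candidates

    with _stage("assign"):
        pooled_reads = []
        for bed in cfg.ribo_beds:
            pooled_reads.extend(
                filter_by_length(read_bed6(bed), f.min_read_len, f.max_read_len)
            )
        calls: list[TranslationCall] = []
        unassigned: dict[str, int] = {}
        smorfs_by_tx: dict[str, list[SmORF]] = {}
        for s in smorfs:
            smorfs_by_tx.setdefault(s.transcript_id, []).append(s)
        tms = {t.transcript_id: t for g in genes for t in g.transcripts}
        for tid, tx_smorfs in sorted(smorfs_by_tx.items()):
            tm = tms[tid]
            positions = assign_footprints(pooled_reads, tm, f.psite_offset, unassigned)
            calls.extend(
                call_translated(tx_smorfs, positions, f, cfg.require_in_frame)
            )
        diagnostics.update({f"assign_{k}": v for k, v in unassigned.items()})

    with _stage("call"):
        called = [c for c in calls if c.called]
        support = {c.smorf.smorf_id: c.footprint_count for c in calls}
        unique_called = deduplicate_smorfs([c.smorf for c in called], support)
    summary["funnel"]["smorfs_called"] = len(called)
    summary["funnel"]["smorfs_called_unique"] = len(unique_called)
    summary["funnel"]["genes_with_called_smorf"] = len(
        {s.gene_id for s in unique_called}
    )
    summary["in_frame"] = in_frame_summary(calls)

    with _stage("summarize"):
        result = PipelineResult(genes, table, passing, common, smorfs, calls, summary)
        _write_outputs(result, unique_called, cfg.outdir)
    return result


def _write_outputs(
    result: PipelineResult, unique_called: list[SmORF], outdir: Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.table.to_frame().to_csv(outdir / "expression.tsv", sep="\t", index=False)
    smorf_rows = [
        {
            "smorf_id": s.smorf_id,
            "gene_id": s.gene_id,
            "transcript_id": s.transcript_id,
            "start": s.start,
            "cds_end": s.cds_end,
            "frame": s.frame,
            "nt_length": s.nt_length,
            "aa_length": s.aa_length,
            "aa_sequence": s.aa_sequence,
        }
        for s in result.smorfs
    ]
    pd.DataFrame(
        smorf_rows,
        columns=["smorf_id", "gene_id", "transcript_id", "start", "cds_end",
                 "frame", "nt_length", "aa_length", "aa_sequence"],
    ).to_csv(outdir / "smorfs.tsv", sep="\t", index=False)
    call_rows = []
    for c in result.calls:
        fr = c.frame_fractions
        call_rows.append(
            {
                "smorf_id": c.smorf.smorf_id,
                "gene_id": c.smorf.gene_id,
                "footprint_count": c.footprint_count,
                "frame0": fr[0] if fr else "",
                "frame1": fr[1] if fr else "",
                "frame2": fr[2] if fr else "",
                "in_frame": c.in_frame,
                "called": c.called,
            }
        )
    pd.DataFrame(
        call_rows,
        columns=["smorf_id", "gene_id", "footprint_count", "frame0", "frame1",
                 "frame2", "in_frame", "called"],
    ).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    with open(outdir / "microproteins.fa", "w") as fh:
        for s in unique_called:
            fh.write(f">{s.smorf_id} gene={s.gene_id} aa={s.aa_length}\n")
            fh.write(s.aa_sequence + "\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def evaluate_recovery(
    calls: list[TranslationCall], truth: list[TruthRecord]
) -> dict[str, float]:
    """Sensitivity and false-discovery proportion of calls vs planted truth.

    Sensitivity: fraction of planted lncRNA smORFs whose exact
    transcript-space interval is called. A called smORF is a false
    discovery iff it overlaps no planted interval on its transcript
    (overlapping/nested ORFs inside a planted ORF necessarily share its
    footprints, so overlap, not identity, defines a true discovery).
    """
    planted = {
        (r.transcript_id, r.start, r.stop_end)
        for r in truth
        if r.planted and r.gene_class == "lncRNA"
    }
    planted_by_tx: dict[str, list[tuple[int, int]]] = {}
    for tid, s, e in planted:
        planted_by_tx.setdefault(tid, []).append((s, e))

    called = [c for c in calls if c.called]
    recovered = sum(
        1
        for tid, s, e in planted
        if any(
            c.smorf.transcript_id == tid and c.smorf.start == s and c.smorf.stop_end == e
            for c in called
        )
    )
    false = sum(
        1
        for c in called
        if not any(
            s < c.smorf.stop_end and c.smorf.start < e
            for s, e in planted_by_tx.get(c.smorf.transcript_id, [])
        )
    )
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "sensitivity": recovered / len(planted) if planted else float("nan"),
        "fdp": false / len(called) if called else 0.0,
    }
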