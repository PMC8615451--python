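"""Transcript models from GTF + FASTA, and genome/transcript coordinate maps.

All internal coordinates are 0-based half-open. GTF input (1-based closed)
and BED output (0-based half-open) are converted at the boundary, nowhere
else. Transcript coordinates run 5'->3' of the transcript: on the minus
strand the genomically *last* exonic base is transcript position 0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pyfaidx
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: sentinel returned by :func:`genomic_to_transcript` for non-exonic positions
NOT_EXONIC = -1

#: default GENCODE-style biotype -> class mapping; overridable at load time
DEFAULT_BIOTYPE_MAP: dict[str, str] = {
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "processed_transcript": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "bidirectional_promoter_lncRNA": "lncRNA",
    "3prime_overlapping_ncRNA": "lncRNA",
    "protein_coding": "protein_coding",
}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One isoform: ordered exons plus its spliced (5'->3') sequence."""

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str
    exons: list[GenomicInterval]
    spliced_sequence: str

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"transcript {self.transcript_id} mixes chromosomes/strands"
            )
        self.exons.sort(key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
        if self.spliced_sequence and len(self.spliced_sequence) != self.spliced_length:
            raise ValueError(
                f"transcript {self.transcript_id}: sequence length "
                f"{len(self.spliced_sequence)} != exon span {self.spliced_length}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    """A gene: its isoforms plus the disjoint union of all their exons."""

    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    transcripts: list[TranscriptModel]
    exon_union: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exon_union and self.transcripts:
            self.exon_union = merge_intervals(
                [e for t in self.transcripts for e in t.exons]
            )

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def union_length(self) -> int:
        return sum(len(e) for e in self.exon_union)


def merge_intervals(exons: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal disjoint cover of a set of intervals on one chrom/strand."""
    exons = sorted(exons, key=lambda e: e.start)
    if not exons:
        return []
    merged = [exons[0]]
    for e in exons[1:]:
        last = merged[-1]
        if e.start <= last.end:
            if e.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, e.end, last.strand)
        else:
            merged.append(e)
    return merged


def _classify(raw_biotype: str, biotype_map: Mapping[str, str]) -> str:
    cls = biotype_map.get(raw_biotype)
    if cls is None:
        logger.warning("unknown biotype %r classified as 'other'", raw_biotype)
        return "other"
    return cls


def _fetch_spliced(fasta: pyfaidx.Fasta, exons: list[GenomicInterval]) -> str:
    chrom = exons[0].chrom
    if chrom not in fasta:
        raise KeyError(f"chromosome {chrom!r} missing from FASTA")
    parts = [str(fasta[chrom][e.start : e.end]).upper() for e in exons]
    seq = "".join(parts)
    if exons[0].strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def load_annotation(
    gtf_path: str | Path,
    fasta_path: str | Path,
    biotype_map: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Parse a GENCODE-dialect GTF + genome FASTA into :class:`GeneModel` s.

    GTF coordinates (1-based closed) are converted to internal 0-based
    half-open intervals. Every transcript gets its spliced sequence
    (reverse-complemented on the minus strand). Genes are classified into
    {lncRNA, protein_coding, other} via ``biotype_map``; unmapped biotypes
    fall to "other" with a logged warning. A chromosome referenced by the
    GTF but absent from the FASTA is a hard error naming the chromosome.
    """
    if biotype_map is None:
        biotype_map = DEFAULT_BIOTYPE_MAP
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    fasta = pyfaidx.Fasta(str(fasta_path))

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes["gene_id"][0]
        gene_name = g.attributes.get("gene_name", [gene_id])[0]
        raw_bt = (
            g.attributes.get("gene_type", g.attributes.get("gene_biotype", ["?"]))
        )[0]
        biotype = _classify(raw_bt, biotype_map)
        transcripts = []
        for t in db.children(g, featuretype="transcript", order_by="start"):
            tid = t.attributes["transcript_id"][0]
            exons = [
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
                for e in db.children(t, featuretype="exon", order_by="start")
            ]
            if not exons:
                raise ValueError(f"transcript {tid} has zero exons")
            seq = _fetch_spliced(fasta, sorted(exons, key=lambda e: e.start))
            transcripts.append(
                TranscriptModel(tid, gene_id, gene_name, biotype, exons, seq)
            )
        if not transcripts:
            raise ValueError(f"gene {gene_id} has zero transcripts")
        genes.append(GeneModel(gene_id, gene_name, biotype, g.seqid, transcripts))
    return genes


def genomic_to_transcript(tm: TranscriptModel, pos: int) -> int:
    """Map a 0-based genomic position to a transcript position.

    Returns :data:`NOT_EXONIC` for intronic/intergenic positions, never
    raises. Bijective over exonic positions; on the minus strand the
    genomically last exonic base maps to transcript position 0.
    """
    offset = 0
    hit = None
    for e in tm.exons:
        if e.start <= pos < e.end:
            hit = offset + (pos - e.start)
            break
        offset += len(e)
    if hit is None:
        return NOT_EXONIC
    if tm.strand == "-":
        return tm.spliced_length - 1 - hit
    return hit


def transcript_to_genomic(
    tm: TranscriptModel, start: int, end: int
) -> list[GenomicInterval]:
    """Project a transcript-space [start, end) back to genomic blocks.

    Blocks come out sorted genomically and their lengths sum to end-start.
    Out-of-range intervals are a hard error.
    """
    if not (0 <= start < end <= tm.spliced_length):
        raise ValueError(
            f"interval [{start}, {end}) out of range for transcript "
            f"{tm.transcript_id} of length {tm.spliced_length}"
        )
    if tm.strand == "-":
        start, end = tm.spliced_length - end, tm.spliced_length - start
    blocks: list[GenomicInterval] = []
    offset = 0
    for e in tm.exons:
        lo = max(start, offset)
        hi = min(end, offset + len(e))
        if lo < hi:
            blocks.append(
                GenomicInterval(e.chrom, e.start + lo - offset, e.start + hi - offset, e.strand)
            )
        offset += len(e)
    return blocks


def write_transcripts_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Export every transcript as one BED12 line (0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                chrom_start = t.exons[0].start
                chrom_end = t.exons[-1].end
                sizes = ",".join(str(len(e)) for e in t.exons)
                starts = ",".join(str(e.start - chrom_start) for e in t.exons)
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            str(chrom_start),
                            str(chrom_end),
                            t.transcript_id,
                            "0",
                            t.strand,
                            str(chrom_start),
                            str(chrom_start),
                            "0",
                            str(len(t.exons)),
                            sizes + ",",
                            starts + ",",
                        ]
                    )
                    + "\n"
                )
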