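"""Gene-level exonic counting, TPM normalisation and expression filtering.

Quantification follows the gene-level "reads in exons" scheme: a read counts
for a gene iff it overlaps the gene's exon union by at least one base, reads
hitting the exon unions of more than one gene are discarded as ambiguous,
and each read is counted at most once. TPM is computed on pooled counts with
the exon-union length as the length term; the read-count cut-off uses the
replicate average. Thresholds are inclusive (>=) for expression filters; the
per-smORF footprint criterion downstream is exclusive (> min).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel, GenomicInterval

ROLES = ("ribo", "total", "poly")


@dataclass(frozen=True)
class FootprintAlignment:
    """One aligned read (ribosome-protected fragment) in genome space."""

    read_id: str
    interval: GenomicInterval

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class FilterConfig:
    """Thresholds of the expression and translation filters.

    min_reads and the TPM cut-offs are inclusive; min_smorf_reads_exclusive
    is exclusive (a call needs strictly more footprints than it).
    """

    min_reads: float = 10.0
    tpm_lnc: float = 2.0
    tpm_coding: float = 5.0
    min_orf_nt: int = 50
    min_smorf_reads_exclusive: int = 10
    psite_offset: int = 0
    min_read_len: int = 20
    max_read_len: int = 36

    def __post_init__(self) -> None:
        for name in ("min_reads", "tpm_lnc", "tpm_coding", "min_orf_nt",
                     "min_smorf_reads_exclusive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def read_bed6(path: str | Path) -> list[FootprintAlignment]:
    """Load alignments from BED6 (name = read id, score = read length)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            out.append(
                FootprintAlignment(
                    name, GenomicInterval(chrom, int(start), int(end), strand.strip())
                )
            )
    return out


def write_bed6(alignments: Iterable[FootprintAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            iv = a.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{a.read_id}\t{a.length}\t{iv.strand}\n"
            )


def filter_by_length(
    alignments: Iterable[FootprintAlignment], min_len: int = 20, max_len: int = 36
) -> list[FootprintAlignment]:
    """Drop too-short (<min_len) and too-long (>max_len) reads."""
    return [a for a in alignments if min_len <= a.length <= max_len]


def _union_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        for e in g.exon_union:
            trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, g)
    return trees


def count_exonic_reads(
    alignments: Iterable[FootprintAlignment],
    genes: Sequence[GeneModel],
    stranded: bool = False,
    diagnostics: dict[str, int] | None = None,
) -> dict[str, int]:
    """Count reads per gene against exon unions (order-independent).

    A read overlapping the exon unions of k > 1 genes is discarded as
    ambiguous; a read on a chromosome absent from the annotation is skipped.
    Both drop classes are tallied in ``diagnostics`` ("ambiguous",
    "unassigned_chrom") when a dict is supplied.
    """
    trees = _union_trees(genes)
    counts = {g.gene_id: 0 for g in genes}
    diag = diagnostics if diagnostics is not None else {}
    diag.setdefault("ambiguous", 0)
    diag.setdefault("unassigned_chrom", 0)
    for a in alignments:
        tree = trees.get(a.interval.chrom)
        if tree is None:
            diag["unassigned_chrom"] += 1
            continue
        hits = {
            h.data.gene_id: h.data
            for h in tree.overlap(a.interval.start, a.interval.end)
            if not stranded or h.data.strand == a.interval.strand
        }
        if len(hits) == 1:
            counts[next(iter(hits))] += 1
        elif len(hits) > 1:
            diag["ambiguous"] += 1
    return counts


def pool_replicates(
    replicate_counts: Sequence[Mapping[str, int]],
) -> tuple[dict[str, int], dict[str, float]]:
    """Per-gene pooled (sum) and replicate-average (mean) counts."""
    if not replicate_counts:
        raise ValueError("zero replicates supplied")
    gene_ids = set().union(*(r.keys() for r in replicate_counts))
    pooled = {g: sum(r.get(g, 0) for r in replicate_counts) for g in gene_ids}
    n = len(replicate_counts)
    average = {g: pooled[g] / n for g in gene_ids}
    return pooled, average


def compute_tpm(
    counts: Mapping[str, float], lengths: Mapping[str, int]
) -> dict[str, float]:
    """TPM_g = 1e6 * (c_g / L_g) / sum_j (c_j / L_j); all-zero -> all-zero."""
    rates = {}
    for g, c in counts.items():
        length = lengths[g]
        if length <= 0:
            raise ValueError(f"gene {g} has non-positive effective length {length}")
        rates[g] = c / length
    total = sum(rates.values())
    if total == 0:
        return {g: 0.0 for g in counts}
    return {g: 1e6 * r / total for g, r in rates.items()}


@dataclass
class ExpressionTable:
    """Gene x role x replicate counts with derived averages and TPM.

    ``replicate_counts[role]`` is a genes-by-replicates integer DataFrame;
    derived columns (pooled, replicate average, TPM) are computed once at
    construction. Effective length is the gene's exon-union length.
    """

    gene_class: dict[str, str]
    lengths: dict[str, int]
    replicate_counts: dict[str, pd.DataFrame]
    _derived: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    @classmethod
    def from_counts(
        cls,
        genes: Sequence[GeneModel],
        role_counts: Mapping[str, Sequence[Mapping[str, int]]],
    ) -> "ExpressionTable":
        gene_ids = [g.gene_id for g in genes]
        frames = {}
        for role, reps in role_counts.items():
            if not reps:
                raise ValueError(f"role {role!r} has zero replicates")
            frames[role] = pd.DataFrame(
                {f"rep{i + 1}": [r.get(g, 0) for g in gene_ids] for i, r in enumerate(reps)},
                index=gene_ids,
            )
        return cls(
            gene_class={g.gene_id: g.biotype for g in genes},
            lengths={g.gene_id: g.union_length for g in genes},
            replicate_counts=frames,
        )

    def derived(self, role: str) -> pd.DataFrame:
        """pooled / avg_count / tpm per gene for one dataset role."""
        if role not in self.replicate_counts:
            raise KeyError(f"dataset role {role!r} absent from table")
        if role not in self._derived:
            reps = self.replicate_counts[role]
            pooled = reps.sum(axis=1)
            avg = reps.mean(axis=1)
            tpm = compute_tpm(pooled.to_dict(), self.lengths)
            self._derived[role] = pd.DataFrame(
                {
                    "pooled": pooled,
                    "avg_count": avg,
                    "tpm": pd.Series(tpm),
                    "gene_class": pd.Series(self.gene_class),
                }
            )
        return self._derived[role]

    def to_frame(self) -> pd.DataFrame:
        """Flat export: one row per gene x role with counts and derived values."""
        parts = []
        for role in self.replicate_counts:
            d = self.derived(role).copy()
            d.insert(0, "role", role)
            reps = self.replicate_counts[role]
            for c in reps.columns:
                d[c] = reps[c]
            d.index.name = "gene_id"
            parts.append(d.reset_index())
        return pd.concat(parts, ignore_index=True)


def filter_expressed(
    table: ExpressionTable, role: str, cfg: FilterConfig
) -> dict[str, set[str]]:
    """Gene ids passing the expression cut-off for one role, split by class.

    lncRNA: replicate-average count >= min_reads and TPM >= tpm_lnc;
    protein_coding: same count rule with TPM >= tpm_coding. Class "other"
    appears in neither result set.
    """
    d = table.derived(role)
    out: dict[str, set[str]] = {"lncRNA": set(), "protein_coding": set()}
    for cls, tpm_min in (("lncRNA", cfg.tpm_lnc), ("protein_coding", cfg.tpm_coding)):
        mask = (
            (d["gene_class"] == cls)
            & (d["avg_count"] >= cfg.min_reads)
            & (d["tpm"] >= tpm_min)
        )
        out[cls] = set(d.index[mask])
    return out


def intersect_datasets(*passing_sets: set[str]) -> set[str]:
    """Exact n-way intersection of per-role passing gene sets."""
    if not passing_sets:
        return set()
    return set.intersection(*map(set, passing_sets))


def tpm_conservation(table: ExpressionTable, role: str) -> float:
    """Sum of TPM over genes for one role (1e6 when any count is positive)."""
    return float(np.sum(table.derived(role)["tpm"].to_numpy()))
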