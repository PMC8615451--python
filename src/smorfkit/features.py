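"""Feature comparison of ribosome-associated lncRNAs vs protein-coding genes.

Extracts per-gene structural features (length, GC content, exon count,
chromosome, expression) on the longest isoform and compares classes with
nonparametric tests. The U statistic follows the pair-count convention
U = sum_ij [x_i > y_j] + 1/2 [x_i = y_j]; p-values are exact by enumeration
for small tie-free samples and normal-approximated with tie correction
otherwise. P-values are reported raw (no multiplicity correction by
default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .quant import ExpressionTable

logger = logging.getLogger(__name__)

#: minimum sequence length for the folding-energy comparison
MFE_MIN_LENGTH = 200


@dataclass
class FeatureSummary:
    gene_id: str
    gene_class: str
    transcript_length: int
    gc_fraction: float
    exon_count: int
    chrom: str
    tpm: dict[str, float]
    mfe: float | None = None


def gc_fraction(seq: str) -> float:
    """GC fraction with N bases excluded from numerator and denominator."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def extract_features(
    genes: list[GeneModel],
    table: ExpressionTable | None = None,
    mfe: dict[str, float] | None = None,
) -> list[FeatureSummary]:
    """One :class:`FeatureSummary` per gene, on the longest spliced isoform."""
    out = []
    for g in genes:
        rep = max(g.transcripts, key=lambda t: (t.spliced_length, t.transcript_id))
        tpm = {}
        if table is not None:
            for role in table.replicate_counts:
                tpm[role] = float(table.derived(role)["tpm"].get(g.gene_id, 0.0))
        out.append(
            FeatureSummary(
                gene_id=g.gene_id,
                gene_class=g.biotype,
                transcript_length=rep.spliced_length,
                gc_fraction=gc_fraction(rep.spliced_sequence),
                exon_count=len(rep.exons),
                chrom=g.chrom,
                tpm=tpm,
                mfe=(mfe or {}).get(g.gene_id),
            )
        )
    return out


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U of x over y with a two-sided p-value.

    Exact enumeration for tie-free samples with both n <= 20, otherwise the
    normal approximation with tie correction.
    """
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    tie_free = len(set(x) | set(y)) == len(x) + len(y)
    method = "exact" if (tie_free and len(x) <= 20 and len(y) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_test(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D = sup|ECDF_x - ECDF_y|, asymptotic p."""
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def chromosome_distribution(features: list[FeatureSummary]) -> pd.DataFrame:
    """Per-chromosome gene counts and TPM sums, tallied per class.

    Counts partition the input: the "n_genes" column sums to len(features).
    """
    rows = []
    for f in features:
        row = {"chrom": f.chrom, "gene_class": f.gene_class, "n_genes": 1}
        for role, v in f.tpm.items():
            row[f"tpm_{role}"] = v
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["chrom", "gene_class", "n_genes"])
    df = pd.DataFrame(rows)
    return df.groupby(["chrom", "gene_class"], as_index=False).sum()


def compare_classes(
    features: list[FeatureSummary],
    class_a: str = "lncRNA",
    class_b: str = "protein_coding",
) -> pd.DataFrame:
    """Mann-Whitney comparisons of length, GC, exon count and TPM by class."""
    fa = [f for f in features if f.gene_class == class_a]
    fb = [f for f in features if f.gene_class == class_b]
    rows = []
    axes = [
        ("transcript_length", lambda f: f.transcript_length),
        ("gc_fraction", lambda f: f.gc_fraction),
        ("exon_count", lambda f: f.exon_count),
    ]
    roles = sorted({r for f in features for r in f.tpm})
    for role in roles:
        axes.append((f"tpm_{role}", lambda f, role=role: f.tpm.get(role, 0.0)))
    for name, get in axes:
        u, p = mann_whitney_u([get(f) for f in fa], [get(f) for f in fb])
        rows.append({"feature": name, "test": "mann_whitney_u", "U": u, "p_value": p})
    return pd.DataFrame(rows)


def mfe_comparison(
    mfe_by_group: dict[str, dict[str, float | None]],
    lengths_by_group: dict[str, dict[str, int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cumulative-distribution table and pairwise KS tests on folding energies.

    ``mfe_by_group`` maps group label (e.g. lncRNA, coding, 5'UTR, 3'UTR) to
    {sequence id: MFE in kcal/mol}; entries with missing MFE are dropped with
    a logged count, and sequences shorter than ``MFE_MIN_LENGTH`` nt are
    excluded when lengths are supplied. Returns (ecdf table, ks table).
    """
    clean: dict[str, list[float]] = {}
    for group, values in mfe_by_group.items():
        lengths = (lengths_by_group or {}).get(group, {})
        kept, missing, short = [], 0, 0
        for sid, v in values.items():
            if v is None:
                missing += 1
                continue
            if sid in lengths and lengths[sid] < MFE_MIN_LENGTH:
                short += 1
                continue
            kept.append(float(v))
        if missing or short:
            logger.warning(
                "group %s: dropped %d missing-MFE and %d short (<%d nt) entries",
                group, missing, short, MFE_MIN_LENGTH,
            )
        if kept:
            clean[group] = sorted(kept)
        else:
            logger.warning("group %s excluded: no usable MFE values", group)

    ecdf_rows = [
        {"group": g, "mfe": v, "ecdf": (i + 1) / len(vals)}
        for g, vals in clean.items()
        for i, v in enumerate(vals)
    ]
    groups = sorted(clean)
    ks_rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            d, p = ks_test(clean[ga], clean[gb])
            ks_rows.append({"group_a": ga, "group_b": gb, "D": d, "p_value": p})
    return pd.DataFrame(ecdf_rows), pd.DataFrame(ks_rows)
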