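"""Synthetic toy study: genome, annotation, footprints, RNA-seq counts, truth.

The generator emulates the statistical structure the downstream analysis
assumes: a toy multi-chromosome genome carrying lncRNA and protein-coding
genes (1-4 exons, both strands); a planted AUG-initiated smORF in each
translated lncRNA and a long planted ORF in each coding gene; ribosome
footprints whose lengths centre on 28 nt (clipped to the 20-36 nt window)
and whose 5' ends show 3-nt periodicity over translated intervals, over a
uniform exonic background; and negative-binomial gene-level counts for the
total and polysomal RNA-seq fractions, with lncRNA means drawn lower than
coding means. Everything is deterministic given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import GeneModel, GenomicInterval, TranscriptModel
from .orfs import DEFAULT_MIN_ORF_NT, STOP_CODONS, enumerate_smorfs
from .quant import FootprintAlignment

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
_STOPS = sorted(STOP_CODONS)

#: chromosomes genes are distributed over (round-robin)
_CHROMS = ("chrS1", "chrS2", "chrS3", "chrS4")
_INTERGENIC_GAP = 200


@dataclass
class SimulationConfig:
    """Knobs of the toy study; defaults are the study conditions."""

    seed: int = 0
    n_lncrna: int = 40
    n_coding: int = 40
    frac_lncrna_translated: float = 0.5
    footprint_length_mean: float = 28.0
    footprint_length_sd: float = 2.0
    periodicity_weight: float = 0.7
    reads_per_translated_smorf: float = 30.0
    background_rate: float = 5.0  # footprints per kb of untranslated exonic seq
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    #: planted microprotein length range (aa), spanning the 18-154 aa regime
    smorf_aa_range: tuple[int, int] = (17, 160)
    #: spliced lncRNA length range (nt)
    lncrna_length_range: tuple[int, int] = (400, 1500)
    #: depth multiplier for the planted ORF of coding genes
    coding_depth_factor: float = 3.0

    def validate(self) -> None:
        counts = ("n_lncrna", "n_coding", "n_replicates")
        for name in counts:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_lncrna_translated", "periodicity_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.reads_per_translated_smorf < 0 or self.background_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.smorf_aa_range
        if 3 * lo + 9 > self.lncrna_length_range[0]:
            raise ValueError(
                "infeasible config: shortest lncRNA cannot hold the smallest "
                f"planted smORF ({3 * lo + 3} nt body+stop)"
            )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one enumerable smORF in the toy study.

    ``planted`` marks deliberately translated ORFs (footprints are placed on
    them); incidental AUG-initiated ORFs arising by chance in the random
    sequence are listed with planted=False.
    """

    gene_id: str
    transcript_id: str
    start: int  # transcript-space position of the A of ATG
    stop_end: int  # exclusive end of the stop codon
    planted: bool
    gene_class: str = "lncRNA"


@dataclass
class _Locus:
    """Internal: one simulated gene before serialisation."""

    gene_id: str
    gene_name: str
    biotype_label: str  # raw GTF biotype string
    gene_class: str
    strand: str
    spliced_seq: str
    exon_lengths: list[int]
    orf: tuple[int, int] | None  # planted (start, stop_end) in transcript space


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _plant_orf(rng: np.random.Generator, seq: str, aa_len: int) -> tuple[str, int, int]:
    """Overwrite a random stretch of ``seq`` with an ATG..stop ORF body."""
    body_nt = 3 * aa_len + 3
    if body_nt > len(seq):
        raise ValueError(
            f"transcript of {len(seq)} nt too short for a {aa_len}-aa smORF"
        )
    start = int(rng.integers(0, len(seq) - body_nt + 1))
    codons = ["ATG"] + [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), aa_len - 1)
    ] + [_STOPS[rng.integers(0, 3)]]
    new = seq[:start] + "".join(codons) + seq[start + body_nt :]
    return new, start, start + body_nt


def _split_exons(rng: np.random.Generator, total: int, n_exons: int) -> list[int]:
    if n_exons == 1:
        return [total]
    cuts = np.sort(rng.choice(np.arange(1, total), size=n_exons - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [total]])
    return list(np.diff(bounds).astype(int))


def _simulate_loci(cfg: SimulationConfig, rng: np.random.Generator) -> list[_Locus]:
    loci: list[_Locus] = []
    n_translated = round(cfg.n_lncrna * cfg.frac_lncrna_translated)
    aa_lo, aa_hi = cfg.smorf_aa_range
    len_lo, len_hi = cfg.lncrna_length_range
    for i in range(cfg.n_lncrna):
        tlen = int(rng.integers(len_lo, len_hi + 1))
        seq = _random_seq(rng, tlen, gc=0.40)
        orf = None
        if i < n_translated:
            max_aa = min(aa_hi, (tlen - 3) // 3 - 1)
            aa_len = int(rng.integers(aa_lo, max_aa + 1))
            seq, start, stop_end = _plant_orf(rng, seq, aa_len)
            orf = (start, stop_end)
        n_exons = int(rng.choice([1, 2, 3, 4], p=[0.4, 0.3, 0.2, 0.1]))
        loci.append(
            _Locus(
                gene_id=f"SIMLNC{i:04d}",
                gene_name=f"lnc-{i}",
                biotype_label="lncRNA",
                gene_class="lncRNA",
                strand="+" if rng.random() < 0.5 else "-",
                spliced_seq=seq,
                exon_lengths=_split_exons(rng, tlen, n_exons),
                orf=orf,
            )
        )
    for i in range(cfg.n_coding):
        orf_aa = int(rng.integers(150, 351))
        utr5 = int(rng.integers(50, 301))
        utr3 = int(rng.integers(50, 301))
        tlen = utr5 + 3 * orf_aa + 3 + utr3
        seq = _random_seq(rng, tlen, gc=0.52)
        codons = ["ATG"] + [
            _SENSE_CODONS[j] for j in rng.integers(0, len(_SENSE_CODONS), orf_aa - 1)
        ] + [_STOPS[rng.integers(0, 3)]]
        seq = seq[:utr5] + "".join(codons) + seq[utr5 + 3 * orf_aa + 3 :]
        n_exons = int(rng.integers(2, 5))
        loci.append(
            _Locus(
                gene_id=f"SIMCOD{i:04d}",
                gene_name=f"cod-{i}",
                biotype_label="protein_coding",
                gene_class="protein_coding",
                strand="+" if rng.random() < 0.5 else "-",
                spliced_seq=seq,
                exon_lengths=_split_exons(rng, tlen, n_exons),
                orf=(utr5, utr5 + 3 * orf_aa + 3),
            )
        )
    return loci


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _layout_genome(
    loci: list[_Locus], rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, list[GenomicInterval]]]:
    """Place loci round-robin on chromosomes; returns sequences and exon maps."""
    chrom_parts: dict[str, list[str]] = {c: [] for c in _CHROMS}
    cursors = {c: 0 for c in _CHROMS}
    exon_map: dict[str, list[GenomicInterval]] = {}
    for idx, locus in enumerate(loci):
        chrom = _CHROMS[idx % len(_CHROMS)]
        gap = _random_seq(rng, _INTERGENIC_GAP, gc=0.45)
        chrom_parts[chrom].append(gap)
        cursors[chrom] += len(gap)
        # genomic exon sequence, genomic order: revcomp of spliced for '-'
        genome_seq = (
            locus.spliced_seq if locus.strand == "+" else _revcomp(locus.spliced_seq)
        )
        exon_lens = (
            locus.exon_lengths if locus.strand == "+" else locus.exon_lengths[::-1]
        )
        exons: list[GenomicInterval] = []
        offset = 0
        for elen in exon_lens:
            intron = _random_seq(rng, int(rng.integers(50, 301)), gc=0.45)
            start = cursors[chrom]
            chrom_parts[chrom].append(genome_seq[offset : offset + elen])
            cursors[chrom] += elen
            exons.append(GenomicInterval(chrom, start, start + elen, locus.strand))
            offset += elen
            if offset < len(genome_seq):
                chrom_parts[chrom].append(intron)
                cursors[chrom] += len(intron)
        exon_map[locus.gene_id] = exons
    return {c: "".join(parts) for c, parts in chrom_parts.items()}, exon_map


def _truth_for_locus(
    locus: _Locus, tm: TranscriptModel, min_orf_nt: int
) -> list[TruthRecord]:
    records = []
    planted = locus.orf
    for s in enumerate_smorfs(tm, min_orf_nt):
        is_planted = planted is not None and (s.start, s.stop_end) == planted
        records.append(
            TruthRecord(
                locus.gene_id,
                tm.transcript_id,
                s.start,
                s.stop_end,
                planted=is_planted,
                gene_class=locus.gene_class,
            )
        )
    if planted is not None and not any(r.planted for r in records):
        raise AssertionError(
            f"planted ORF of {locus.gene_id} not recovered by enumeration"
        )
    return records


def simulate_annotation(
    cfg: SimulationConfig,
    outdir: str | Path,
    min_orf_nt: int = DEFAULT_MIN_ORF_NT,
) -> tuple[Path, Path, list[TruthRecord]]:
    """Write genome.fa, annotation.gtf and truth.tsv; return their paths + truth.

    Deterministic given cfg.seed (byte-identical files on re-run). Truth
    records cover every enumerable smORF of every simulated transcript, with
    planted ORFs flagged.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 0])
    loci = _simulate_loci(cfg, rng)
    chrom_seqs, exon_map = _layout_genome(loci, rng)

    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom in _CHROMS:
            fh.write(f">{chrom}\n")
            seq = chrom_seqs[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    gtf_path = outdir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        for locus in loci:
            exons = exon_map[locus.gene_id]
            tid = locus.gene_id + ".t1"
            attrs = (
                f'gene_id "{locus.gene_id}"; transcript_id "{tid}"; '
                f'gene_type "{locus.biotype_label}"; gene_name "{locus.gene_name}";'
            )
            g_start, g_end = exons[0].start + 1, exons[-1].end
            chrom = exons[0].chrom
            fh.write(
                f"{chrom}\tsim\tgene\t{g_start}\t{g_end}\t.\t{locus.strand}\t.\t"
                f'gene_id "{locus.gene_id}"; gene_type "{locus.biotype_label}"; '
                f'gene_name "{locus.gene_name}";\n'
            )
            fh.write(
                f"{chrom}\tsim\ttranscript\t{g_start}\t{g_end}\t.\t{locus.strand}\t.\t{attrs}\n"
            )
            for e in exons:
                fh.write(
                    f"{chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{locus.strand}\t.\t{attrs}\n"
                )

    truth: list[TruthRecord] = []
    for locus in loci:
        tm = TranscriptModel(
            locus.gene_id + ".t1",
            locus.gene_id,
            locus.gene_name,
            locus.gene_class,
            exon_map[locus.gene_id],
            locus.spliced_seq,
        )
        truth.extend(_truth_for_locus(locus, tm, min_orf_nt))

    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tstart\tstop_end\tplanted\tgene_class\n")
        for r in truth:
            fh.write(
                f"{r.gene_id}\t{r.transcript_id}\t{r.start}\t{r.stop_end}\t"
                f"{int(r.planted)}\t{r.gene_class}\n"
            )
    return fasta_path, gtf_path, truth


def read_truth(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            g, t, s, e, p, c = line.rstrip("\n").split("\t")
            records.append(TruthRecord(g, t, int(s), int(e), bool(int(p)), c))
    return records


def _draw_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    ln = round(rng.normal(cfg.footprint_length_mean, cfg.footprint_length_sd))
    return int(min(36, max(20, ln)))


def _transcript_index(genes: list[GeneModel]) -> dict[str, TranscriptModel]:
    return {t.transcript_id: t for g in genes for t in g.transcripts}


def _emit_read(
    tm: TranscriptModel, p5: int, length: int, read_id: str
) -> FootprintAlignment:
    """Genomic single-block read anchored at the transcript 5' base ``p5``."""
    from .annotation import transcript_to_genomic

    g5 = transcript_to_genomic(tm, p5, p5 + 1)[0].start
    if tm.strand == "+":
        iv = GenomicInterval(tm.chrom, g5, g5 + length, "+")
    else:
        iv = GenomicInterval(tm.chrom, max(0, g5 - length + 1), g5 + 1, "-")
    return FootprintAlignment(read_id, iv)


def simulate_footprints(
    cfg: SimulationConfig,
    truth: list[TruthRecord],
    genes: list[GeneModel],
    replicate: int,
) -> list[FootprintAlignment]:
    """Ribosome footprints for one replicate of the "ribo" role.

    Planted ORFs receive ~Poisson(reads_per_translated_smorf) footprints
    (coding ORFs scaled by coding_depth_factor) whose 5' ends are
    codon-uniform over [start, stop_end) with frame 0 probability
    ``periodicity_weight`` (remainder split equally over frames 1 and 2).
    Background footprints fall uniformly on exonic sequence outside planted
    ORFs at ``background_rate`` per kb. Deterministic given (seed, replicate).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1, replicate])
    tms = _transcript_index(genes)
    reads: list[FootprintAlignment] = []
    serial = 0

    for rec in (r for r in truth if r.planted):
        tm = tms[rec.transcript_id]
        lam = cfg.reads_per_translated_smorf * (
            cfg.coding_depth_factor if rec.gene_class == "protein_coding" else 1.0
        )
        n = rng.poisson(lam)
        n_codons = (rec.stop_end - rec.start) // 3
        for _ in range(n):
            codon = int(rng.integers(0, n_codons))
            u = rng.random()
            if u < cfg.periodicity_weight:
                frame = 0
            else:
                frame = 1 if (u - cfg.periodicity_weight) < (1 - cfg.periodicity_weight) / 2 else 2
            p5 = rec.start + 3 * codon + frame
            if p5 >= tm.spliced_length:
                p5 = tm.spliced_length - 1
            reads.append(
                _emit_read(tm, p5, _draw_length(cfg, rng), f"rep{replicate}_r{serial}")
            )
            serial += 1

    planted_by_tx: dict[str, list[tuple[int, int]]] = {}
    for r in truth:
        if r.planted:
            planted_by_tx.setdefault(r.transcript_id, []).append((r.start, r.stop_end))
    for g in genes:
        for tm in g.transcripts:
            blocked = planted_by_tx.get(tm.transcript_id, [])
            free = [
                p
                for p in range(tm.spliced_length)
                if not any(s <= p < e for s, e in blocked)
            ]
            if not free:
                continue
            n_bg = rng.poisson(cfg.background_rate * len(free) / 1000.0)
            for _ in range(n_bg):
                p5 = free[int(rng.integers(0, len(free)))]
                reads.append(
                    _emit_read(
                        tm, p5, _draw_length(cfg, rng), f"rep{replicate}_b{serial}"
                    )
                )
                serial += 1
    return reads


def _nb_draw(rng: np.random.Generator, mu: float, alpha: float, size: int) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha*mu^2."""
    if mu <= 0:
        return np.zeros(size, dtype=int)
    if alpha < 1e-9:
        return rng.poisson(mu, size=size)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p, size=size)


def simulate_counts(
    cfg: SimulationConfig, genes: list[GeneModel]
) -> dict[str, list[dict[str, int]]]:
    """Gene-level counts for the "total" and "poly" roles, per replicate.

    Gene-specific means are drawn log-uniformly, lncRNA means an order of
    magnitude below coding means; replicate counts are negative binomial
    with dispersion ``nb_dispersion``. Deterministic given the seed.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 2])
    mus = {}
    for g in genes:
        if g.biotype == "protein_coding":
            mu = float(np.exp(rng.uniform(np.log(800), np.log(8000))))
        else:
            mu = float(np.exp(rng.uniform(np.log(80), np.log(800))))
        mus[g.gene_id] = mu
    out: dict[str, list[dict[str, int]]] = {}
    for role in ("total", "poly"):
        reps: list[dict[str, int]] = [dict() for _ in range(cfg.n_replicates)]
        for g in genes:
            draws = _nb_draw(rng, mus[g.gene_id], cfg.nb_dispersion, cfg.n_replicates)
            for i in range(cfg.n_replicates):
                reps[i][g.gene_id] = int(draws[i])
        out[role] = reps
    return out


def write_counts_tsv(reps: list[dict[str, int]], path: str | Path) -> None:
    gene_ids = sorted(reps[0])
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(f"rep{i + 1}" for i in range(len(reps))) + "\n")
        for g in gene_ids:
            fh.write(g + "\t" + "\t".join(str(r.get(g, 0)) for r in reps) + "\n")


def simulate_study(cfg: SimulationConfig, outdir: str | Path) -> dict[str, object]:
    """Generate a complete toy study on disk and return its file manifest.

    Writes genome.fa, annotation.gtf, truth.tsv, ribo_rep{i}.bed and
    {total,poly}_counts.tsv under ``outdir``; byte-identical given the seed.
    """
    from .annotation import load_annotation
    from .quant import write_bed6

    outdir = Path(outdir)
    fasta, gtf, truth = simulate_annotation(cfg, outdir)
    genes = load_annotation(gtf, fasta)
    ribo_beds = []
    for rep in range(1, cfg.n_replicates + 1):
        reads = simulate_footprints(cfg, truth, genes, rep)
        bed = outdir / f"ribo_rep{rep}.bed"
        write_bed6(reads, bed)
        ribo_beds.append(bed)
    counts = simulate_counts(cfg, genes)
    paths = {}
    for role in ("total", "poly"):
        p = outdir / f"{role}_counts.tsv"
        write_counts_tsv(counts[role], p)
        paths[role] = p
    return {
        "fasta": fasta,
        "gtf": gtf,
        "truth": outdir / "truth.tsv",
        "ribo_beds": ribo_beds,
        "total_counts": paths["total"],
        "poly_counts": paths["poly"],
        "truth_records": truth,
        "genes": genes,
    }


def read_counts_tsv(path: str | Path) -> list[dict[str, int]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        reps: list[dict[str, int]] = [dict() for _ in header]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            for i, v in enumerate(parts[1:]):
                reps[i][parts[0]] = int(v)
    return reps
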