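import random

import pytest

from smorfkit.annotation import GenomicInterval, TranscriptModel

BASES = "ACGT"
RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(RC)[::-1]


def single_exon_tm(seq: str, strand: str = "+", start: int = 100,
                   tid: str = "T1", gid: str = "G1",
                   biotype: str = "lncRNA") -> TranscriptModel:
    """A one-exon transcript whose spliced sequence is ``seq``."""
    return TranscriptModel(
        tid, gid, gid, biotype,
        [GenomicInterval("chrT", start, start + len(seq), strand)], seq,
    )


def random_multi_exon_tm(rng: random.Random, strand: str,
                         tid: str = "T1") -> TranscriptModel:
    """A random 1-5 exon transcript with a consistent spliced sequence."""
    n_exons = rng.randint(1, 5)
    exons = []
    pos = rng.randint(0, 50)
    for _ in range(n_exons):
        length = rng.randint(3, 60)
        exons.append(GenomicInterval("chrT", pos, pos + length, strand))
        pos += length + rng.randint(10, 40)
    genome_seq = "".join(rng.choice(BASES) for _ in range(sum(len(e) for e in exons)))
    spliced = genome_seq if strand == "+" else revcomp(genome_seq)
    return TranscriptModel(tid, "G1", "G1", "lncRNA", exons, spliced)


@pytest.fixture(scope="session")
def toy_study(tmp_path_factory):
    """One simulated study shared by the slower end-to-end tests."""
    from smorfkit import SimulationConfig, simulate_study

    outdir = tmp_path_factory.mktemp("toy_study")
    cfg = SimulationConfig(seed=7)
    return cfg, simulate_study(cfg, outdir)


@pytest.fixture(scope="session")
def toy_run(toy_study, tmp_path_factory):
    from smorfkit import RunConfig, run_pipeline

    cfg, m = toy_study
    outdir = tmp_path_factory.mktemp("toy_run")
    rc = RunConfig(m["fasta"], m["gtf"], m["ribo_beds"], m["total_counts"],
                   m["poly_counts"], outdir)
    return rc, run_pipeline(rc)
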