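"""Contracts of the synthetic-study generator."""
import numpy as np
import pytest

from smorfkit.annotation import load_annotation
from smorfkit.occupancy import assign_footprints, count_in_smorf
from smorfkit.orfs import enumerate_smorfs
from smorfkit.quant import compute_tpm
from smorfkit.simulate import (
    SimulationConfig,
    _nb_draw,
    read_truth,
    simulate_annotation,
    simulate_counts,
    simulate_footprints,
)


@pytest.fixture(scope="module")
def small_study(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim_small")
    cfg = SimulationConfig(seed=3, n_lncrna=10, n_coding=6, n_replicates=1)
    fasta, gtf, truth = simulate_annotation(cfg, outdir)
    genes = load_annotation(gtf, fasta)
    return cfg, fasta, gtf, truth, genes


class TestSimulateAnnotation:
    def test_translated_count_forced_by_config(self, small_study):
        _, _, _, truth, _ = small_study
        planted_lnc = [r for r in truth if r.planted and r.gene_class == "lncRNA"]
        assert len(planted_lnc) == 5  # 10 lncRNAs * 0.5

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=11, n_lncrna=4, n_coding=2, n_replicates=1)
        fa1, gtf1, _ = simulate_annotation(cfg, tmp_path / "a")
        fa2, gtf2, _ = simulate_annotation(cfg, tmp_path / "b")
        assert fa1.read_bytes() == fa2.read_bytes()
        assert gtf1.read_bytes() == gtf2.read_bytes()

    def test_planted_smorfs_rediscovered_from_emitted_files(self, small_study):
        """100% of planted intervals are found by enumeration on the files."""
        _, _, _, truth, genes = small_study
        tms = {t.transcript_id: t for g in genes for t in g.transcripts}
        for r in truth:
            if not r.planted:
                continue
            found = {(s.start, s.stop_end) for s in enumerate_smorfs(tms[r.transcript_id])}
            assert (r.start, r.stop_end) in found

    def test_truth_roundtrip_through_tsv(self, small_study, tmp_path):
        cfg, _, _, truth, _ = small_study
        _, _, truth2 = simulate_annotation(cfg, tmp_path / "again")
        assert read_truth(tmp_path / "again" / "truth.tsv") == truth2 == truth

    def test_genes_on_both_strands_and_multi_exon(self, small_study):
        _, _, _, _, genes = small_study
        strands = {g.strand for g in genes}
        assert strands == {"+", "-"}
        assert any(len(g.transcripts[0].exons) > 1 for g in genes)

    def test_infeasible_config_hard_error(self):
        cfg = SimulationConfig(smorf_aa_range=(200, 300),
                               lncrna_length_range=(300, 400))
        with pytest.raises(ValueError, match="infeasible"):
            cfg.validate()


class TestSimulateFootprints:
    def test_full_periodicity_puts_every_5p_end_in_frame_zero(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_lncrna=6, n_coding=0,
                               frac_lncrna_translated=1.0,
                               periodicity_weight=1.0, background_rate=0.0,
                               n_replicates=1)
        fasta, gtf, truth = simulate_annotation(cfg, tmp_path)
        genes = load_annotation(gtf, fasta)
        reads = simulate_footprints(cfg, truth, genes, replicate=1)
        tms = {t.transcript_id: t for g in genes for t in g.transcripts}
        for r in truth:
            if not r.planted:
                continue
            positions = assign_footprints(reads, tms[r.transcript_id])
            inside = [p for p in positions if r.start <= p < r.stop_end]
            assert inside and all((p - r.start) % 3 == 0 for p in inside)

    def test_no_translation_no_background_empty(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_lncrna=4, n_coding=0,
                               frac_lncrna_translated=0.0, background_rate=0.0,
                               n_replicates=1)
        fasta, gtf, truth = simulate_annotation(cfg, tmp_path)
        genes = load_annotation(gtf, fasta)
        assert simulate_footprints(cfg, truth, genes, replicate=1) == []

    def test_lengths_in_window_and_centred(self, small_study):
        cfg, _, _, truth, genes = small_study
        reads = simulate_footprints(cfg, truth, genes, replicate=1)
        lengths = np.array([r.length for r in reads])
        assert lengths.min() >= 20 and lengths.max() <= 36
        assert abs(lengths.mean() - 28) < 1.0

    def test_mean_footprint_count_matches_rate(self, tmp_path):
        """Monte-Carlo check: planted-smORF counts average the configured rate."""
        cfg = SimulationConfig(seed=21, n_lncrna=4, n_coding=0,
                               frac_lncrna_translated=1.0, background_rate=0.0,
                               reads_per_translated_smorf=30, n_replicates=1)
        fasta, gtf, truth = simulate_annotation(cfg, tmp_path)
        genes = load_annotation(gtf, fasta)
        tms = {t.transcript_id: t for g in genes for t in g.transcripts}
        planted = [r for r in truth if r.planted]
        counts = []
        for rep in range(1, 201):
            reads = simulate_footprints(cfg, truth, genes, replicate=rep)
            for r in planted:
                positions = assign_footprints(reads, tms[r.transcript_id])
                counts.append(sum(r.start <= p < r.stop_end for p in positions))
        assert np.mean(counts) == pytest.approx(30, abs=2)


class TestSimulateCounts:
    def test_poisson_limit_as_dispersion_vanishes(self):
        rng = np.random.default_rng(0)
        draws = _nb_draw(rng, mu=50.0, alpha=1e-12, size=10_000)
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.1)

    def test_zero_mean_zero_counts(self):
        rng = np.random.default_rng(0)
        assert _nb_draw(rng, 0.0, 0.1, 100).sum() == 0

    def test_dispersion_inflates_variance(self):
        rng = np.random.default_rng(1)
        draws = _nb_draw(rng, mu=100.0, alpha=0.5, size=20_000)
        # var = mu + alpha mu^2 = 5100
        assert draws.var() == pytest.approx(5100, rel=0.15)

    def test_lncrna_tpm_below_coding_tpm(self, tmp_path):
        """Configured mean separation shows up as a class TPM difference."""
        cfg = SimulationConfig(seed=9, n_lncrna=250, n_coding=250, n_replicates=1)
        fasta, gtf, truth = simulate_annotation(cfg, tmp_path)
        genes = load_annotation(gtf, fasta)
        counts = simulate_counts(cfg, genes)["total"][0]
        tpm = compute_tpm(counts, {g.gene_id: g.union_length for g in genes})
        lnc = np.median([tpm[g.gene_id] for g in genes if g.biotype == "lncRNA"])
        cod = np.median([tpm[g.gene_id] for g in genes if g.biotype == "protein_coding"])
        assert lnc < cod

    def test_determinism(self, small_study):
        cfg, _, _, _, genes = small_study
        assert simulate_counts(cfg, genes) == simulate_counts(cfg, genes)
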