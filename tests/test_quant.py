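"""Exonic counting, TPM normalisation, expression filters, intersection."""
import random

import pytest

from smorfkit.annotation import GeneModel, GenomicInterval
from smorfkit.quant import (
    ExpressionTable,
    FilterConfig,
    FootprintAlignment,
    compute_tpm,
    count_exonic_reads,
    filter_by_length,
    filter_expressed,
    intersect_datasets,
    pool_replicates,
)

from conftest import single_exon_tm


def _gene(gid, exons, biotype="lncRNA"):
    tms = [single_exon_tm("A" * (e.end - e.start), strand=e.strand,
                          start=e.start, tid=f"{gid}.t{i}", gid=gid,
                          biotype=biotype)
           for i, e in enumerate(exons)]
    # rebuild chrom names on the provided exons
    for tm, e in zip(tms, exons):
        tm.exons = [e]
    return GeneModel(gid, gid, biotype, exons[0].chrom, tms)


def _read(chrom, start, end, strand="+", rid="r"):
    return FootprintAlignment(rid, GenomicInterval(chrom, start, end, strand))


class TestCountExonicReads:
    def test_one_base_overlap_counts(self):
        g = _gene("G1", [GenomicInterval("chr1", 10, 15, "+")])
        counts = count_exonic_reads([_read("chr1", 12, 40)], [g])
        assert counts["G1"] == 1

    def test_intronic_read_not_counted(self):
        g = _gene("G1", [GenomicInterval("chr1", 10, 15, "+")])
        assert count_exonic_reads([_read("chr1", 20, 48)], [g])["G1"] == 0

    def test_ambiguous_read_discarded_and_tallied(self):
        g1 = _gene("G1", [GenomicInterval("chr1", 10, 50, "+")])
        g2 = _gene("G2", [GenomicInterval("chr1", 40, 90, "+")])
        diag = {}
        counts = count_exonic_reads([_read("chr1", 45, 48)], [g1, g2],
                                    diagnostics=diag)
        assert counts == {"G1": 0, "G2": 0}
        assert diag["ambiguous"] == 1

    def test_unknown_chromosome_skipped_and_tallied(self):
        g = _gene("G1", [GenomicInterval("chr1", 10, 15, "+")])
        diag = {}
        count_exonic_reads([_read("chrX", 10, 14)], [g], diagnostics=diag)
        assert diag["unassigned_chrom"] == 1

    def test_stranded_mode_requires_matching_strand(self):
        g = _gene("G1", [GenomicInterval("chr1", 10, 50, "+")])
        counts = count_exonic_reads([_read("chr1", 12, 40, strand="-")], [g],
                                    stranded=True)
        assert counts["G1"] == 0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_per_base_oracle(self, trial):
        """Counting equals brute-force base-set intersection on small cases."""
        rng = random.Random(trial)
        genes = []
        for i in range(rng.randint(1, 5)):
            exons = sorted(rng.sample(range(0, 900, 10), rng.randint(1, 3)))
            genes.append(_gene(
                f"G{i}",
                [GenomicInterval("chr1", s, s + rng.randint(5, 40), "+")
                 for s in exons],
            ))
        reads = [_read("chr1", s, s + rng.randint(20, 36), rid=f"r{j}")
                 for j, s in enumerate(rng.choices(range(0, 1000), k=50))]
        base_sets = {
            g.gene_id: {b for e in g.exon_union for b in range(e.start, e.end)}
            for g in genes
        }
        expected = {g.gene_id: 0 for g in genes}
        for r in reads:
            bases = set(range(r.interval.start, r.interval.end))
            hits = [gid for gid, bs in base_sets.items() if bases & bs]
            if len(hits) == 1:
                expected[hits[0]] += 1
        assert count_exonic_reads(reads, genes) == expected

    def test_order_independence(self):
        rng = random.Random(3)
        g = _gene("G1", [GenomicInterval("chr1", 10, 500, "+")])
        reads = [_read("chr1", s, s + 28, rid=f"r{j}")
                 for j, s in enumerate(rng.choices(range(0, 600), k=30))]
        shuffled = reads[:]
        rng.shuffle(shuffled)
        assert count_exonic_reads(reads, [g]) == count_exonic_reads(shuffled, [g])


class TestLengthFilter:
    def test_window_inclusive(self):
        reads = [_read("c", 0, n, rid=str(n)) for n in (19, 20, 28, 36, 37)]
        kept = {r.read_id for r in filter_by_length(reads)}
        assert kept == {"20", "28", "36"}


class TestTpm:
    def test_single_gene_gets_the_whole_million(self):
        assert compute_tpm({"A": 7}, {"A": 500}) == {"A": 1e6}

    def test_equal_rates_equal_tpm(self):
        tpm = compute_tpm({"A": 10, "B": 30}, {"A": 1000, "B": 3000})
        assert tpm["A"] == pytest.approx(500000)
        assert tpm["B"] == pytest.approx(500000)

    def test_hand_evaluated_example(self):
        tpm = compute_tpm({"A": 2, "B": 1}, {"A": 100, "B": 100})
        assert tpm["A"] == pytest.approx(666666.67, abs=0.01)
        assert tpm["B"] == pytest.approx(333333.33, abs=0.01)

    def test_all_zero_counts_give_zero_tpm(self):
        assert compute_tpm({"A": 0, "B": 0}, {"A": 10, "B": 10}) == {"A": 0.0, "B": 0.0}

    def test_zero_length_is_hard_error_naming_gene(self):
        with pytest.raises(ValueError, match="GBAD"):
            compute_tpm({"GBAD": 1}, {"GBAD": 0})

    def test_conservation_on_random_counts(self):
        rng = random.Random(11)
        counts = {f"G{i}": rng.randint(0, 500) for i in range(200)}
        counts["G0"] = 1  # ensure at least one positive
        lengths = {g: rng.randint(200, 3000) for g in counts}
        total = sum(compute_tpm(counts, lengths).values())
        assert total == pytest.approx(1e6, rel=1e-9)


class TestPoolReplicates:
    def test_pool_and_average(self):
        pooled, avg = pool_replicates([{"G": 10}, {"G": 20}])
        assert pooled["G"] == 30 and avg["G"] == 15

    def test_single_replicate_identity(self):
        pooled, avg = pool_replicates([{"G": 7}])
        assert pooled["G"] == 7 and avg["G"] == 7

    def test_zero_replicates_hard_error(self):
        with pytest.raises(ValueError):
            pool_replicates([])


def _table(lnc_counts, cod_counts, lnc_len=1000, cod_len=1000):
    genes = [
        _gene("L1", [GenomicInterval("chr1", 0, lnc_len, "+")], "lncRNA"),
        _gene("C1", [GenomicInterval("chr1", 5000, 5000 + cod_len, "+")],
              "protein_coding"),
    ]
    return ExpressionTable.from_counts(
        genes, {"ribo": [{"L1": c, "C1": k} for c, k in zip(lnc_counts, cod_counts)]}
    )


class TestFilterExpressed:
    def test_lncrna_thresholds_inclusive(self):
        # avg 10 and TPM exactly 2 must pass (>= rule)
        genes = [
            _gene("L1", [GenomicInterval("chr1", 0, 1000, "+")], "lncRNA"),
            _gene("C1", [GenomicInterval("chr1", 5000, 6000, "+")], "protein_coding"),
        ]
        # TPM of L1 = 1e6 * 10 / (10 + 4990) = 2000... craft exact 2:
        # rates: L1 10/1000=0.01; want 1e6*0.01/total=2 -> total=5000 -> C1 rate 4999.99
        table = ExpressionTable.from_counts(
            genes, {"ribo": [{"L1": 10, "C1": 4999990}]}
        )
        assert table.derived("ribo").loc["L1", "tpm"] == pytest.approx(2.0)
        passing = filter_expressed(table, "ribo", FilterConfig())
        assert "L1" in passing["lncRNA"]

    def test_count_rule_is_conjunctive(self):
        t = _table([9, 10], [0, 0])  # avg 9.5 < 10 despite huge TPM
        passing = filter_expressed(t, "ribo", FilterConfig())
        assert "L1" not in passing["lncRNA"]

    def test_coding_uses_stricter_tpm(self):
        genes = [
            _gene("C1", [GenomicInterval("chr1", 0, 1000, "+")], "protein_coding"),
            _gene("C2", [GenomicInterval("chr1", 5000, 6000, "+")], "protein_coding"),
        ]
        # C1 TPM = 1e6*100/(100+x); choose x so TPM = 4.9 -> fails 5
        x = 100 * (1e6 / 4.9 - 1)
        table = ExpressionTable.from_counts(
            genes, {"ribo": [{"C1": 100, "C2": int(round(x))}]}
        )
        assert table.derived("ribo").loc["C1", "tpm"] == pytest.approx(4.9, rel=1e-4)
        passing = filter_expressed(table, "ribo", FilterConfig())
        assert "C1" not in passing["protein_coding"]

    def test_other_class_excluded(self):
        g = _gene("O1", [GenomicInterval("chr1", 0, 1000, "+")], "other")
        table = ExpressionTable.from_counts(g and [g], {"ribo": [{"O1": 100}]})
        passing = filter_expressed(table, "ribo", FilterConfig())
        assert passing["lncRNA"] == set() and passing["protein_coding"] == set()

    def test_absent_role_hard_error(self):
        t = _table([10], [10])
        with pytest.raises(KeyError):
            filter_expressed(t, "poly", FilterConfig())

    def test_monotone_in_thresholds(self):
        rng = random.Random(2)
        genes = [
            _gene(f"L{i}", [GenomicInterval("chr1", i * 2000, i * 2000 + 1000, "+")],
                  "lncRNA")
            for i in range(20)
        ]
        counts = [{g.gene_id: rng.randint(0, 50) for g in genes}]
        table = ExpressionTable.from_counts(genes, {"ribo": counts})
        base = filter_expressed(table, "ribo", FilterConfig())["lncRNA"]
        for cfg in (FilterConfig(min_reads=15), FilterConfig(tpm_lnc=1e5)):
            assert filter_expressed(table, "ribo", cfg)["lncRNA"] <= base


class TestIntersect:
    def test_three_way(self):
        assert intersect_datasets({"A", "B"}, {"B", "C"}, {"B"}) == {"B"}

    def test_empty_input_empties_output(self):
        assert intersect_datasets({"A"}, set(), {"A"}) == set()

    def test_identical_sets_fixed_point(self):
        s = {"A", "B", "C"}
        assert intersect_datasets(s, s, s) == s
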