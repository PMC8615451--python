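"""The packaged microprotein reference table and its structural validation.

The package ships a 35-row table of ribosome-occupied lncRNA smORFs and
their predicted microproteins (data/table2_microproteins.tsv). Each record
obeys three structural invariants: the ORF nt length is exactly 3x the
peptide length (stop codon excluded), the peptide string has exactly that
length, and every peptide starts with M. One caveat is inherited from the
source: the tail (residues 61-93) of the 93-aa MIR22HG peptide is a
synthetic poly-G placeholder, flagged in the file header; lengths and
identifiers of that row are genuine.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Table2Record:
    gene_name: str
    ensembl_gene_id: str
    orf_nt_length: int
    mp_aa_length: int
    localization: str | None
    localization_score: str | None
    aa_sequence: str

    def violations(self) -> list[str]:
        """Structural-invariant violations of this record (empty = valid)."""
        out = []
        if self.orf_nt_length != 3 * self.mp_aa_length:
            out.append(
                f"{self.gene_name}: nt length {self.orf_nt_length} != "
                f"3 x {self.mp_aa_length}"
            )
        if len(self.aa_sequence) != self.mp_aa_length:
            out.append(
                f"{self.gene_name}: sequence length {len(self.aa_sequence)} != "
                f"{self.mp_aa_length}"
            )
        if not self.aa_sequence.startswith("M"):
            out.append(f"{self.gene_name}: sequence does not start with M")
        if set(self.aa_sequence) - _AA20:
            out.append(f"{self.gene_name}: non-standard residues in sequence")
        return out


def packaged_fixture_path() -> Path:
    return Path(resources.files("smorfkit").joinpath("data/table2_microproteins.tsv"))


def load_table2(path: str | Path | None = None) -> list[Table2Record]:
    """Parse the microprotein table ('-' localization parses as absent)."""
    path = Path(path) if path is not None else packaged_fixture_path()
    records = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if header is None:
                header = line.rstrip("\n").split("\t")
                continue
            d = dict(zip(header, line.rstrip("\n").split("\t")))
            records.append(
                Table2Record(
                    gene_name=d["gene_name"],
                    ensembl_gene_id=d["ensembl_gene_id"],
                    orf_nt_length=int(d["orf_nt_length"]),
                    mp_aa_length=int(d["mp_aa_length"]),
                    localization=None if d["localization"] == "-" else d["localization"],
                    localization_score=(
                        None if d["localization_score"] == "-" else d["localization_score"]
                    ),
                    aa_sequence=d["aa_sequence"],
                )
            )
    return records


def validate_table2(path: str | Path | None = None) -> tuple[bool, list[str]]:
    """Check every record's invariants; returns (all pass, violation list)."""
    violations = []
    for rec in load_table2(path):
        violations.extend(rec.violations())
    return (not violations, violations)


def _round_half_up(x: float) -> int:
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def summarize_microproteins(records: list[Table2Record]) -> dict:
    """Summary statistics over microprotein records.

    The mean peptide length is the arithmetic mean rounded half-up to an
    integer; n_genes counts distinct Ensembl gene ids.
    """
    if not records:
        return {
            "n_smorfs": 0, "n_genes": 0, "mean_aa_length": None,
            "min_aa_length": None, "max_aa_length": None, "min_nt_length": None,
        }
    aa = [r.mp_aa_length for r in records]
    return {
        "n_smorfs": len(records),
        "n_genes": len({r.ensembl_gene_id for r in records}),
        "mean_aa_length": _round_half_up(sum(aa) / len(aa)),
        "min_aa_length": min(aa),
        "max_aa_length": max(aa),
        "min_nt_length": min(r.orf_nt_length for r in records),
    }
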