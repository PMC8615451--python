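"""Enumeration of canonical AUG-initiated small ORFs in transcript space.

An ORF's nucleotide length excludes the stop codon, so nt_length is always
3x the peptide length (a 156-nt ORF body encodes a 52-aa microprotein).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Data.CodonTable import standard_dna_table

from .annotation import TranscriptModel

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
_CODON_TABLE = standard_dna_table.forward_table

#: default minimum ORF body length in nt; multiples of 3 make 51 nt (17 aa)
#: the effective floor
DEFAULT_MIN_ORF_NT = 50


class UntranslatableCodonError(ValueError):
    """Raised for codons that cannot be translated (N or internal stop)."""


@dataclass(frozen=True)
class SmORF:
    """One AUG-initiated ORF in transcript coordinates.

    ``start`` is the transcript position of the A of AUG; ``cds_end`` is the
    exclusive end of the last sense codon (the stop codon sits at
    [cds_end, stop_end)).
    """

    smorf_id: str
    transcript_id: str
    gene_id: str
    start: int
    cds_end: int
    aa_sequence: str

    @property
    def stop_end(self) -> int:
        return self.cds_end + 3

    @property
    def frame(self) -> int:
        return self.start % 3

    @property
    def nt_length(self) -> int:
        return self.cds_end - self.start

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)


def translate(codons: str) -> str:
    """Translate a codon string with the standard genetic code.

    The input must be a whole number of sense codons: a codon containing N
    (or any non-ACGT base) and an in-frame stop codon both raise
    :class:`UntranslatableCodonError`, which :func:`enumerate_smorfs`
    consumes by dropping the offending ORF.
    """
    if len(codons) % 3:
        raise ValueError(f"codon string length {len(codons)} not divisible by 3")
    aa = []
    for i in range(0, len(codons), 3):
        codon = codons[i : i + 3]
        if codon in STOP_CODONS:
            raise UntranslatableCodonError(f"in-frame stop codon {codon} at {i}")
        try:
            aa.append(_CODON_TABLE[codon])
        except KeyError:
            raise UntranslatableCodonError(f"untranslatable codon {codon!r} at {i}")
    return "".join(aa)


def enumerate_smorfs(
    tm: TranscriptModel, min_orf_nt: int = DEFAULT_MIN_ORF_NT
) -> list[SmORF]:
    """All AUG-initiated ORFs of body length >= ``min_orf_nt`` in ``tm``.

    Every ATG in every frame is paired with the nearest downstream in-frame
    stop codon; ORFs without an in-frame stop inside the transcript are
    dropped, as are ORFs whose body contains a codon with N. Nested and
    overlapping ORFs are all kept. Output is sorted by start position.
    """
    seq = tm.spliced_sequence
    out: list[SmORF] = []
    for start in _find_atg(seq):
        cds_end = _nearest_stop(seq, start)
        if cds_end is None:
            continue
        if cds_end - start < min_orf_nt:
            continue
        try:
            aa = translate(seq[start:cds_end])
        except UntranslatableCodonError:
            continue
        out.append(
            SmORF(
                smorf_id=f"{tm.transcript_id}:{start}-{cds_end + 3}",
                transcript_id=tm.transcript_id,
                gene_id=tm.gene_id,
                start=start,
                cds_end=cds_end,
                aa_sequence=aa,
            )
        )
    out.sort(key=lambda s: (s.start, s.cds_end))
    return out


def _find_atg(seq: str):
    i = seq.find("ATG")
    while i != -1:
        yield i
        i = seq.find("ATG", i + 1)


def _nearest_stop(seq: str, start: int) -> int | None:
    for i in range(start + 3, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i
    return None


def deduplicate_smorfs(
    smorfs: Iterable[SmORF],
    footprint_support: Mapping[str, int] | None = None,
) -> list[SmORF]:
    """Collapse smORFs across isoforms to one record per (gene, peptide).

    The representative is the copy on the isoform with the most footprint
    support (``footprint_support`` maps smorf_id -> count); ties fall to the
    lexicographically smallest transcript_id. Identical peptides from
    *different* genes are kept as separate records, as are distinct
    shared-prefix peptides of different lengths.
    """
    support = footprint_support or {}
    best: dict[tuple[str, str], SmORF] = {}
    for s in smorfs:
        key = (s.gene_id, s.aa_sequence)
        cur = best.get(key)
        if cur is None:
            best[key] = s
            continue
        s_sup, c_sup = support.get(s.smorf_id, 0), support.get(cur.smorf_id, 0)
        if s_sup > c_sup or (s_sup == c_sup and s.transcript_id < cur.transcript_id):
            best[key] = s
    return sorted(best.values(), key=lambda s: (s.gene_id, s.start, s.cds_end))
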