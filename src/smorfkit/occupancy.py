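"""Footprint projection onto transcripts, per-smORF counting and calling.

Footprints are reduced to their 5'-most transcribed base (strand-aware),
optionally shifted by a fixed P-site offset, and counted inside the smORF
interval *including* the stop codon [start, stop_end): terminating ribosomes
occupy the stop. The headline translation call is the read-count criterion
alone — strictly more than ``min_smorf_reads_exclusive`` footprints — with
frame modality available as an optional stringency flag.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotation import NOT_EXONIC, TranscriptModel, genomic_to_transcript
from .orfs import SmORF
from .quant import FilterConfig, FootprintAlignment


@dataclass
class TranslationCall:
    """Per-smORF footprint occupancy and the pass/fail translation decision."""

    smorf: SmORF
    footprint_count: int
    frame_fractions: tuple[float, float, float] | None
    called: bool

    @property
    def in_frame(self) -> bool:
        """True iff frame 0 is *strictly* modal among assigned 5' ends."""
        if self.frame_fractions is None:
            return False
        f0, f1, f2 = self.frame_fractions
        return f0 > f1 and f0 > f2


def assign_footprints(
    alignments: Iterable[FootprintAlignment],
    tm: TranscriptModel,
    psite_offset: int = 0,
    unassigned: dict[str, int] | None = None,
) -> list[int]:
    """Transcript-space 5'-end positions of the footprints landing on ``tm``.

    The 5'-most transcribed base is ``interval.start`` on '+' transcripts and
    ``interval.end - 1`` on '-'. A footprint is assigned iff that base is
    exonic; the assigned position is its transcript coordinate plus
    ``psite_offset``, and offset positions beyond the transcript end are
    dropped. Unassignable reads are tallied, never raised.
    """
    tally = unassigned if unassigned is not None else {}
    tally.setdefault("not_exonic", 0)
    tally.setdefault("offset_out_of_range", 0)
    positions: list[int] = []
    for a in alignments:
        if a.interval.chrom != tm.chrom:
            tally["not_exonic"] += 1
            continue
        five_prime = a.interval.start if tm.strand == "+" else a.interval.end - 1
        p = genomic_to_transcript(tm, five_prime)
        if p == NOT_EXONIC:
            tally["not_exonic"] += 1
            continue
        p += psite_offset
        if not (0 <= p < tm.spliced_length):
            tally["offset_out_of_range"] += 1
            continue
        positions.append(p)
    return positions


def count_in_smorf(
    positions: Sequence[int], smorf: SmORF
) -> tuple[int, tuple[float, float, float] | None]:
    """Footprint count and frame-fraction triple for one smORF.

    Counts 5' positions p with start <= p < stop_end; the frame of p is
    (p - start) mod 3. Fractions are undefined (None) at count 0.
    """
    frames = [0, 0, 0]
    for p in positions:
        if smorf.start <= p < smorf.stop_end:
            frames[(p - smorf.start) % 3] += 1
    n = sum(frames)
    if n == 0:
        return 0, None
    return n, tuple(f / n for f in frames)


def call_translated(
    smorfs: Sequence[SmORF],
    positions: Sequence[int],
    cfg: FilterConfig,
    require_in_frame: bool = False,
) -> list[TranslationCall]:
    """Translation calls for smORFs of one transcript.

    Called iff footprint_count > cfg.min_smorf_reads_exclusive, and, when
    ``require_in_frame`` is set, frame 0 is additionally the strict modal
    frame of the assigned 5' ends.
    """
    calls = []
    for s in smorfs:
        n, fractions = count_in_smorf(positions, s)
        call = TranslationCall(s, n, fractions, called=False)
        passed = n > cfg.min_smorf_reads_exclusive
        if passed and require_in_frame:
            passed = call.in_frame
        call.called = passed
        calls.append(call)
    return calls


#: definition string recorded next to every in-frame summary
IN_FRAME_DEFINITION = (
    "a smORF is in-frame iff frame 0 is strictly modal among the 5' ends of "
    "its assigned footprints (smORFs with zero footprints count in the "
    "denominator only)"
)


def in_frame_summary(calls: Iterable[TranslationCall]) -> dict:
    """Total enumerated smORFs, how many are in-frame, and the fraction."""
    calls = list(calls)
    total = len(calls)
    n_in_frame = sum(1 for c in calls if c.footprint_count > 0 and c.in_frame)
    return {
        "total_smorfs": total,
        "in_frame": n_in_frame,
        "fraction_in_frame": n_in_frame / total if total else float("nan"),
        "definition": IN_FRAME_DEFINITION,
    }


def coverage_track(
    alignments: Iterable[FootprintAlignment],
    tm: TranscriptModel,
    window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-base footprint coverage (full alignment span) over a transcript window.

    Each footprint adds +1 to every transcript base its genomic span covers;
    bases outside exons contribute nothing. Default window is the whole
    transcript.
    """
    lo, hi = window if window is not None else (0, tm.spliced_length)
    cov = np.zeros(hi - lo, dtype=int)
    for a in alignments:
        if a.interval.chrom != tm.chrom:
            continue
        for gpos in range(a.interval.start, a.interval.end):
            p = genomic_to_transcript(tm, gpos)
            if p != NOT_EXONIC and lo <= p < hi:
                cov[p - lo] += 1
    return cov


def write_bedgraph(cov: np.ndarray, chrom: str, path, offset: int = 0) -> None:
    """Write a coverage vector as bedGraph intervals of constant value."""
    with open(path, "w") as fh:
        i = 0
        while i < len(cov):
            j = i
            while j < len(cov) and cov[j] == cov[i]:
                j += 1
            if cov[i]:
                fh.write(f"{chrom}\t{offset + i}\t{offset + j}\t{int(cov[i])}\n")
            i = j
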