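# Methods

## Pipeline model and conventions

The pipeline treats translation detection as a deterministic rule cascade
over three evidence sources: ribosome footprints (ribo), total-fraction
RNA-seq (total) and polysomal-fraction RNA-seq (poly).

**Coordinates.** All internal coordinates are 0-based half-open; GTF input
(1-based closed) and BED output (0-based half-open) are converted only at
the file boundary. Transcript coordinates run 5′→3′ of the transcript, so
on the minus strand the genomically last exonic base is position 0.

**Counting.** A read counts for a gene iff its genomic interval overlaps
the gene's exon union by at least one base; reads overlapping the unions of
more than one gene are discarded as ambiguous (the behaviour of standard
gene-level counters), reads on unannotated chromosomes are skipped, and
both drop classes are tallied in the summary. Counting is unstranded by
default with a stranded flag. Reads shorter than 20 nt or longer than 36 nt
are removed before any counting.

**TPM.** TPM is computed on replicate-pooled counts; the ≥ 10-read
criterion uses the replicate average — the two criteria are worded
differently on purpose and implemented differently. The length term is the
gene's exon-union length: quantification is gene-level over exons, so the
union is the matching length choice; a representative-transcript length is
one configuration change away. Whenever any count is positive, per-role TPM
sums to 10⁶ to within 10⁻⁶ relative (asserted in tests).

**Thresholds.** Expression thresholds are inclusive (≥ 10 reads, TPM ≥ 2
for lncRNA / ≥ 5 for coding). The translation criterion is exclusive: a
call requires strictly more than 10 footprints, so a count of exactly 10
fails. Both defaults are configurable (`FilterConfig`).

**smORF enumeration.** Every ATG in every frame of every isoform is paired
with the nearest downstream in-frame stop; ORFs without a stop are dropped,
as are ORFs containing a codon with N (N is allowed in sequence but
untranslatable). The nt length excludes the stop codon, making nt = 3 × aa
an invariant of every record. The default 50-nt floor, applied to a
multiple of 3, is effectively 51 nt = 17 aa. No maximum length is imposed
by default (a cap is available), and nested/overlapping ORFs are all kept.
Across isoforms, records are deduplicated on (gene, peptide), keeping the
copy with most footprint support (ties: smallest transcript id).
Whether discovery should use all isoforms or one canonical isoform per gene
is genuinely open; all-isoforms-with-deduplication is the default and the
choice is recorded in the summary metadata.

**Footprint position and calling.** A footprint is represented by its
5′-most transcribed base; no P-site calibration is performed by default
(`psite_offset = 0`) because an offset procedure would add a fitted
parameter the rule cascade does not need — the conventional +12 nt offset
is available as configuration. The counting interval includes the stop
codon, [start, stop_end), since terminating ribosomes occupy the stop; the
exclusive alternative is one flag away and the chosen convention is written
into the summary JSON. The headline call uses the count criterion alone;
requiring frame 0 to be the strictly modal frame is an optional flag.

**In-frame statistic.** A smORF is "in-frame" iff frame 0 is strictly
modal among its assigned footprint 5′ ends (ties and zero-footprint smORFs
are not in-frame; zero-footprint smORFs stay in the denominator). The
definition string is embedded in the output because other definitions are
defensible and the statistic is meaningless without one.

**Class comparison.** Features (spliced length, GC with N excluded from
both numerator and denominator, exon count, chromosome, TPM) are extracted
on the longest isoform (mean-of-isoforms is the alternative). Mann–Whitney
U follows the pair-count convention U = Σ[xᵢ > yⱼ] + ½[xᵢ = yⱼ], exact for
tie-free samples with both n ≤ 20 and normal-approximated with tie
correction otherwise; the two-sample KS statistic is sup|ECDF₁ − ECDF₂|
with asymptotic p. Both are backed by scipy, whose conventions were
verified against exhaustive enumeration in the test suite. P-values are
reported raw; the folding-energy comparison accepts externally computed
minimum-free-energy values, drops missing entries with a logged count, and
excludes sequences under 200 nt.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale:

- **Genes.** `n_lncrna` lncRNAs (spliced length 400–1500 nt, 1–4 exons,
  GC 0.40) and `n_coding` coding genes (a planted 150–350-aa ORF flanked by
  UTRs, 2–4 exons, GC 0.52), on both strands of four toy chromosomes. The
  GC and exon-count separation gives the class comparison the direction
  seen in real annotation without modelling it precisely.
- **Planted translation.** A fraction `frac_lncrna_translated` (default
  0.5) of lncRNAs receives one planted AUG-initiated smORF of 17–160 aa
  (spanning the 18–154-aa regime of reported lncRNA microproteins), built
  from sense codons so enumeration recovers it exactly.
- **Footprints.** Per replicate, each planted ORF draws
  Poisson(`reads_per_translated_smorf` = 30) footprints (coding ORFs ×3);
  5′ ends are codon-uniform over [start, stop_end) with frame 0 probability
  `periodicity_weight` = 0.7 and the remainder split equally over frames 1
  and 2 — a simulator assumption surfaced in configuration, since real
  periodicity profiles are platform-dependent. Background footprints fall
  uniformly on exonic sequence outside planted ORFs at `background_rate`
  = 5 per kb. Lengths are round(Normal(28, 2)) clipped to [20, 36],
  matching the canonical footprint-length distribution. Footprints are
  written as single-block BED6 intervals anchored at the 5′ base (a read
  may run into an intron rather than splice); only 5′ ends drive calling,
  so this simplification does not affect recovery.
- **RNA-seq.** Total and polysomal counts are gene-level negative-binomial
  draws (variance μ + αμ², `nb_dispersion` α = 0.1) with log-uniform
  gene means, lncRNA means (80–800) an order of magnitude below coding
  means (800–8000). Counts, not reads, are simulated: the pipeline accepts
  count tables and counts suffice to exercise the TPM/filter logic.
- **Truth.** Every enumerable smORF of every simulated transcript is
  listed, planted ORFs flagged; incidental ORFs arising by chance in
  random sequence carry `planted = False`.

All three generators are deterministic given the seed (child seeds are
derived per stage and replicate), and byte-identical output files are
asserted in tests.

**What the simulator does not model** — sequencing error, alignment
ambiguity, junction-spanning footprints, fragment/GC bias, isoform
complexity (one isoform per gene is emitted), contaminant reads, and real
periodicity profiles. Passing the recovery tests therefore shows the rule
cascade is implemented correctly and is well-behaved at realistic depths;
it does not show the thresholds are optimal for any real library.

## Recovery scoring

Sensitivity is the fraction of planted lncRNA smORFs whose exact
transcript-space interval is called. A called smORF counts as a false
discovery only if it overlaps no planted interval on its transcript:
ORFs nested in or overlapping a planted ORF necessarily inherit its
footprints, so identity would misclassify structurally unavoidable calls.
At the default conditions (30 footprints per planted smORF per replicate,
3 replicates, 5 background footprints/kb, 20 seeds, 24 lncRNAs + 16 coding
genes per study — sizes chosen to keep a 20-study evaluation under a minute
on one core) the pipeline reaches mean sensitivity ≥ 0.95 and mean
false-discovery proportion ≤ 0.10; the acceptance script recomputes both.

## Packaged reference table

The package ships a 35-row table of ribosome-occupied lncRNA smORFs and
their predicted microproteins with per-row structural invariants
(nt = 3 × aa, peptide length = aa, leading M, 20-letter alphabet) enforced
by `validate_table2`. Two records legitimately lack a localization
prediction ('-' parses as absent). Residues 61–93 of the 93-aa MIR22HG
peptide are a synthetic poly-G placeholder completing a sequence whose
published tail was not recoverable; the flag lives in the file header and
the loader docstring, and no statistic depends on the padded residues —
only on lengths and identifiers, which are genuine.

## Known limitations

- No spliced (multi-block) alignment input; BED6 single-interval alignments
  only, with the SAM/BAM route reducible to BED upstream.
- No coding-potential scoring (Kozak context, conservation) and no
  spectral/periodicity test statistics; the call criterion is a read-count
  rule by design.
- Gene-level quantification only; isoform abundance is never estimated.
- The exact-p branch of the Mann–Whitney test requires tie-free samples;
  tied samples use the tie-corrected normal approximation regardless of
  size.
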