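# Methods

## Overview

`lrfusion` detects fusion transcripts from splice-aware long-read RNA-seq
alignments in two phases: a fast scan for chimeric reads that nominates
candidate fusion gene pairs, and a supervised requantification step that
models each candidate pair as a fusion contig, realigns the candidate
reads, and tallies read support per breakpoint. The package also contains
the single-cell bookkeeping, the benchmarking framework, and the synthetic
data generator used to validate all of it.

The method assumes a reference genome and a GENCODE-style transcript
annotation: fusion evidence must overlap annotated exons, so chimeras
confined to introns or to unannotated transcribed regions are not
reported. It also assumes the upstream aligner is splice-aware and reports
supplementary/split alignments for chimeric reads (PAF or SAM/BAM input).

## Coordinates

Internally every interval is 0-based, half-open. All reported breakpoints
are 1-based genomic coordinates with strand (`chrom:pos:strand`): the left
breakpoint is the last transcribed base of the 5′ gene, the right
breakpoint the first transcribed base of the 3′ gene. GTF input/output
uses the standard 1-based closed convention and round-trips exactly.

## Phase 1: chimeric read scan

A read is a chimera candidate when it has ≥ 2 alignment segments at
distinct loci. "Distinct" means different chromosomes, opposite alignment
strands, or a same-chromosome gap above `locus_separation` (default
100 kb, matching the neighbor-gene distance used in fusion filtering;
the upstream aligner's own notion of "multiple loci" is not observable
from its output, so the package applies this explicit rule).

Per consecutive segment pair along the read:

- both segments must be assignable to (different) genes — a segment is
  assigned to the gene whose merged exons it overlaps most, with ties to
  the lexicographically smaller gene id; zero exonic overlap means no
  assignment;
- both identities must reach `min_identity` (default 0.70). Identity is
  matches / alignment block length: PAF columns 10/11, or from SAM
  NM+CIGAR ((aligned − NM)/aligned); a missing NM tag falls back to 1.0
  with a warning;
- gene order is read order, flipped when *both* segments align antisense
  to their genes' strands (the read is then the reverse complement of the
  fusion transcript). Mixed sense/antisense pairs keep read order;
- raw breakpoints are the junction-facing genomic ends of the two
  segments; each is scored by its distance to the nearest exon boundary
  *of the assigned gene* (boundaries of all transcripts of the gene; ties
  toward the smaller coordinate).

A read with more than two segments contributes one candidate per
qualifying consecutive pair, at most one per gene pair, so a read never
double-counts. Candidates grouped by ordered gene pair are retained when
some read has both boundary distances ≤ 50 b, or some read has one ≤ 50 b
and the other ≤ 1 kb while the pair has ≥ 2 supporting reads. Retention is
deliberately monotone in read support.

Prefilters then remove pairs on the user-supplied exclusion list
("red herrings"/known normals), pairs of genes with overlapping genomic
spans (strand ignored), paralogous pairs (when a paralog table is
supplied; on by default, disable with `paralog_filter=False`), and pairs
below `min_ffpm` (default 0.1 FFPM = 1 fusion read per 10 M total reads).
FFPM is computed against the total input read count, which must be
supplied when only alignments are given; it is computed before annotation
filtering so filters cannot interact with the expression estimate.

## Phase 2: fusion contigs and breakpoint quantification

Each retained ordered pair becomes one contig: the 5′ gene's collapsed
model (union of exons over all transcripts), then a 1000-base `N` spacer,
then the 3′ gene, all reading 5′→3′ (minus-strand genes are
reverse-complemented). Introns ≤ 1 kb are copied verbatim; longer introns
are represented by their first and last 500 bases, which preserves both
splice dinucleotides. The spacer prevents spurious alignments bridging
the junction without exonic anchor. The construction records an exact
bidirectional coordinate map; the middle of a shrunk intron is explicitly
unmapped.

Realignment is pluggable. `Minimap2Realigner` shells out to minimap2
(`-ax splice`) with the contig as reference and keeps the primary
alignment per read. The default `ProjectionRealigner` replays each
candidate read's phase-1 genomic placement through the coordinate map,
intersected with the assigned genes' exons — the alignment an ideal
splice-aware realignment would produce. It is deterministic, needs no
external process, and is what the test suite's "ideal alignments" use.

Alignment block ends within `snap_dist` (3) bases of a contig exon
boundary are snapped onto it (idempotent; a snap that would collapse a
block is refused). A read is fusion evidence when its cumulative exonic
overlap is ≥ `min_per_side_exon_bp` (25) within each gene, after
subtracting overlap with exon regions flagged sequence-similar between
the two genes (user-supplied table, e.g. precomputed all-vs-all BLASTN
results; absent table disables the filter with a logged note). The read's
breakpoint pair is (end of last 5′-gene block, start of first 3′-gene
block), tallied at exact post-snap coordinates without further smoothing.

Splice classification reads the contig sequence: donor = 2 bases 3′ of
the left break, acceptor = 2 bases 5′ of the right break; the consensus
set defaults to {GT–AG} and can be extended (GC–AG, AT–AC). Breakpoints at
the contig edge are non-consensus with a flag. Final filters per
breakpoint: ≥ 0.1 FFPM; non-consensus breakpoints need ≥ 2 reads
(consensus ≥ 1); within a fusion pair, isoforms under 5% of the dominant
isoform's read count are discarded as noise. The dominant count is taken
over all tallied isoforms *before* the other filters so that every filter
is monotone in its threshold (raising any threshold can only remove
rows). A read supporting several candidate contigs is counted for each
independently.

The report is a TSV sorted by descending read support then fusion name:
`#FusionName, LeftGene, LeftBreakpoint, RightGene, RightBreakpoint,
NumLongReads, LR_FFPM, SpliceType (ONLY_REF_SPLICE | INCL_NON_REF_SPLICE),
Annotations, LongReadIds[, CellBarcodes]`.

Open choices resolved here: the 5% isoform rule compares read counts (at
a fixed total this equals comparing FFPM); the 0.1 FFPM cutoff is applied
per breakpoint (the per-pair aggregate is recoverable by summing rows);
the boundary index uses all transcripts of each gene, not one canonical
transcript; the spacer and intron-flank sizes are declared defaults
exposed in `FusionCallingConfig`.

## Single-cell mode

Barcodes and UMIs are carried in read names as
`<barcode>^<umi>^<core_id>` (delimiter configurable; encode/decode is an
exact inverse pair). From report rows, counts per (cell, fusion) are
distinct UMIs (exact-match deduplication only — no edit-distance
collapsing; reads-per-cell available via a flag). Somatic fusion selection
keeps fusions with ≥ `min_cells` (5) tumor cells, tumor fraction ≥
`min_tumor_fraction` (0.8) among annotated fusion-positive cells
(unannotated barcodes are warned about and excluded from the
denominator), and absence from a matched normal matrix when provided.
Matrix outputs: long TSV and MatrixMarket triplets with barcode/fusion
name files.

## Benchmarking

Gene-pair matching allows each side to match by identity, paralogy, or
genomic-overlap proxy; `strict` preserves 5′→3′ order, `allow_reverse`
also tries the swapped order (strict matches are a subset of
allow-reverse by construction). Breakpoint pairs are order-sorted by
(chrom, pos) before comparison; `exact` requires identity, `fuzzy` a ± 5
base window per breakpoint. One truth entry is counted once as TP no
matter how many predictions hit it; FN are unmatched truth entries; FP
are unmatched predictions, optionally restricted to fusions predicted
uniquely by the method when a cross-method table is given.

PR curves evaluate the metrics at minimum-read-support thresholds
1..max. A threshold retaining zero predictions is reported with
precision 1.0 and a flag, and excluded from the AUC. The AUC is the
trapezoidal integral of precision over recall on recall-sorted points,
extended horizontally to recall 0 from the highest-precision point; it is
validated against a piecewise-linear quadrature oracle to 1e−12.

Proxy truth sets ("wisdom of the crowds") filter each method's calls at a
minimum read support, then keep fusions predicted by ≥ k methods
(unordered pairs, proxies honored); a 3 × 10 grid over k ∈ {2,3,4} and
thresholds 1–10 is provided as a convenience sweep. Nuisance filtering
removes fusions with mitochondrial/HLA/immunoglobulin partners, fusions on
a known-normal list, same-chromosome pairs whose span gap is ≤ 100 kb
(gap between spans, not midpoints; exactly 100 kb is removed), and — when
a cross-sample table is given — fusions containing promiscuous genes
(≥ 2 methods in ≥ 2 samples by default; configurable).

## Synthetic data generator

The simulator emulates the structure the caller exploits, at toy scale:

- genome: by default 20 multi-exon genes (3–6 exons of 80–300 b, introns
  100–2000 b) placed 120 kb apart across 4 chromosomes, so any two genes
  are distinct loci; every intron carries GT..AG on the coding strand,
  making all truth breakpoints consensus splice sites by construction;
- fusions: by default 5 gene pairs joined at internal exon junctions
  (donor never the last exon, acceptor never the first) with 3–8
  supporting reads each; explicit plans allow multi-isoform fusions;
- background: 10 full-length normal-transcript reads per gene (200 reads
  at the defaults);
- errors: i.i.d. per-base substitution/insertion/deletion at configurable
  rates, plus optional 3′-anchored truncation (modeling 3′-biased
  coverage). This is a deliberate simplification of platform error
  models: no homopolymer or quality structure, which suffices to exercise
  identity thresholds and snapping but says nothing about base-caller-
  specific artifacts;
- ideal alignments: emitted pre-error in genome coordinates as PAF, so
  error degrades identity but never placement — exactly the quantity the
  caller's 70% gate tests. Segment identity is
  (exonic length − substitutions − deletions)/(exonic length + insertions);
- truth tables in the benchmarking TSV dialect, and single-cell plans
  that tag reads with planned barcode/UMI counts.

Everything derives from one `numpy` generator seeded by the spec, so all
emitted files are byte-identical under a fixed seed.

What passing tests on this generator do and do not show: exact truth
recovery at 1% error demonstrates the pipeline's bookkeeping (gene order,
coordinate maps, snapping, tallies, filters) is correct, and the error
sweep shows the identity gate behaves as designed; it does not establish
accuracy on real transcriptomes, where alignment ambiguity, paralogy,
incomplete annotation, and library artifacts dominate.

## Numerical and degenerate-input choices

- FFPM is computed as `reads × 10⁶ / total` so the defining case
  1/10 M yields exactly 0.1; zero total reads is an error.
- Boundary-distance ties break toward the smaller genomic coordinate,
  then the smaller gene id; an unindexed chromosome is an error, not 0.
- Precision with zero retained predictions is 1.0-with-flag, excluded
  from AUC; AUC of no usable points is 0 with a flag.
- Empty results still produce a header-only report; writing and reading
  the report is an exact round trip.
- Identity of a zero-length alignment block is defined as 0.

## Problem sizes

The default test and demonstration conditions are the 20-gene / 5-fusion /
200-background-read data sets described above (genome ≈ 3 Mb, a few
hundred reads); these sizes were chosen so each full pipeline run
completes in seconds on a single CPU while still exercising multi-exon,
multi-chromosome, both-strand, and multi-isoform structure.

## Known limitations

- Fusions are modelled strictly as two-gene events; multi-partner
  rearrangements are reported only as their pairwise projections.
- Evidence must overlap annotated exons; intronic/intergenic chimeras and
  partners missing from the annotation are invisible.
- The projection realigner trusts phase-1 placements; true realignment
  (minimap2) is recommended when input alignments are noisy.
- UMI deduplication is exact-match; sequencing errors in UMIs inflate
  counts slightly.
- The benchmarking proxy truth sets are operational constructs, not
  ground truth; they systematically favor consensus behavior.
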