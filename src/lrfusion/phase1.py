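"""Phase 1: candidate chimeric read detection and gene-pair prefiltering.

Splice-aware long-read alignments (PAF or SAM) are scanned for reads whose
segments hit two distinct genomic loci. Each qualifying consecutive segment
pair with per-segment identity >= 70% (default) becomes a chimeric read
candidate carrying an ordered 5'->3' gene pair and raw genomic breakpoints.
Candidates grouped by gene pair are retained when breakpoints sit near
reference exon boundaries (50 b / 1 kb rules), then annotation-, overlap-,
paralog- and expression-level (FFPM) prefilters are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .annotation import ExonBoundaryIndex, GeneModelSet, SimilarityMap
from .config import DEFAULT_CONFIG, FusionCallingConfig

log = logging.getLogger(__name__)


class AlignmentFormatError(ValueError):
    """Input stream is neither PAF nor SAM/BAM."""


@dataclass(frozen=True)
class AlignmentSegment:
    """One aligned block of a read on the genome (0-based half-open)."""

    read_id: str
    read_start: int
    read_end: int
    chrom: str
    genome_start: int
    genome_end: int
    align_strand: str
    matches: int
    block_len: int

    def __post_init__(self) -> None:
        if not self.read_start < self.read_end:
            raise ValueError(f"{self.read_id}: read_start must be < read_end")
        if not self.genome_start < self.genome_end:
            raise ValueError(f"{self.read_id}: genome_start must be < genome_end")
        if self.align_strand not in ("+", "-"):
            raise ValueError(f"{self.read_id}: bad strand {self.align_strand!r}")
        if not 0 <= self.identity <= 1:
            raise ValueError(f"{self.read_id}: identity outside [0, 1]")

    @property
    def identity(self) -> float:
        return self.matches / self.block_len if self.block_len else 0.0


# ---------------------------------------------------------------------------
# alignment input


def read_paf(path):
    """Yield :class:`AlignmentSegment` from a PAF file (12+ columns)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12 or fields[4] not in ("+", "-"):
                raise AlignmentFormatError(f"{path}: line {lineno}: not a PAF record")
            try:
                yield AlignmentSegment(
                    read_id=fields[0],
                    read_start=int(fields[2]),
                    read_end=int(fields[3]),
                    align_strand=fields[4],
                    chrom=fields[5],
                    genome_start=int(fields[7]),
                    genome_end=int(fields[8]),
                    matches=int(fields[9]),
                    block_len=int(fields[10]),
                )
            except ValueError as exc:
                raise AlignmentFormatError(f"{path}: line {lineno}: {exc}") from None


def write_paf(segments, path, read_lengths=None, target_lengths=None) -> None:
    """Write segments as minimal 12-column PAF."""
    read_lengths = read_lengths or {}
    target_lengths = target_lengths or {}
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        s.read_id,
                        read_lengths.get(s.read_id, s.read_end),
                        s.read_start,
                        s.read_end,
                        s.align_strand,
                        s.chrom,
                        target_lengths.get(s.chrom, s.genome_end),
                        s.genome_start,
                        s.genome_end,
                        s.matches,
                        s.block_len,
                        60,
                    )
                )
                + "\n"
            )


def read_sam(path):
    """Yield :class:`AlignmentSegment` from SAM/BAM, including supplementaries."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    warned = False
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary:
                continue
            cig = a.cigartuples or []
            lead_hard = cig[0][1] if cig and cig[0][0] == 5 else 0
            qstart = a.query_alignment_start + lead_hard
            qend = a.query_alignment_end + lead_hard
            read_len = a.infer_read_length() or qend
            if a.is_reverse:
                qstart, qend = read_len - qend, read_len - qstart
            stats = a.get_cigar_stats()[0]
            aligned = stats[0] + stats[7] + stats[8]  # M + = + X
            block_len = aligned + stats[1] + stats[2]  # + I + D
            if a.has_tag("NM"):
                matches = max(0, block_len - int(a.get_tag("NM")))
            else:
                if not warned:
                    log.warning("%s: NM tag absent; assuming perfect identity", path)
                    warned = True
                matches = block_len
            yield AlignmentSegment(
                read_id=a.query_name,
                read_start=qstart,
                read_end=qend,
                chrom=a.reference_name,
                genome_start=a.reference_start,
                genome_end=a.reference_end,
                align_strand="-" if a.is_reverse else "+",
                matches=matches,
                block_len=block_len,
            )


def load_alignments(path):
    """Read PAF or SAM/BAM, sniffing the format from extension/content."""
    path = Path(path)
    if path.suffix in (".sam", ".bam"):
        return list(read_sam(path))
    with open(path, "rb") as fh:
        head = fh.read(4)
    if head[:1] == b"@" or head[:4] == b"BAM\x01" or head[:2] == b"\x1f\x8b":
        return list(read_sam(path))
    return list(read_paf(path))


# ---------------------------------------------------------------------------
# chimeric read collection


def distinct_loci(a: AlignmentSegment, b: AlignmentSegment, config=DEFAULT_CONFIG) -> bool:
    """Two segments map to distinct genomic loci.

    Distinct means: different chromosomes, opposite alignment strands, or a
    same-chromosome gap larger than ``config.locus_separation``.
    """
    if a.chrom != b.chrom:
        return True
    if a.align_strand != b.align_strand:
        return True
    gap = max(a.genome_start, b.genome_start) - min(a.genome_end, b.genome_end)
    return gap > config.locus_separation


def collect_chimeric_reads(alignments, config: FusionCallingConfig = DEFAULT_CONFIG):
    """Group alignments by read, retaining reads hitting >= 2 distinct loci.

    ``alignments`` is an iterable of :class:`AlignmentSegment` or a PAF/SAM
    path. Segments of retained reads are sorted by read coordinate.
    """
    if isinstance(alignments, (str, Path)):
        alignments = load_alignments(alignments)
    by_read: dict[str, list[AlignmentSegment]] = {}
    for seg in alignments:
        by_read.setdefault(seg.read_id, []).append(seg)
    out: dict[str, list[AlignmentSegment]] = {}
    for read_id, segs in by_read.items():
        if len(segs) < 2:
            continue
        segs.sort(key=lambda s: (s.read_start, s.read_end))
        if any(
            distinct_loci(segs[i], segs[j], config)
            for i in range(len(segs))
            for j in range(i + 1, len(segs))
        ):
            out[read_id] = segs
    return out


# ---------------------------------------------------------------------------
# candidate derivation


def assign_segment_gene(segment: AlignmentSegment, gms: GeneModelSet) -> str | None:
    """Gene whose exons the segment overlaps most (>= 1 base), else None.

    A segment wholly confined to introns or intergenic space is not gene
    evidence. Ties go to the lexicographically smaller gene id.
    """
    overlaps = gms.exonic_overlap(segment.chrom, segment.genome_start, segment.genome_end)
    if not overlaps:
        return None
    return min(overlaps, key=lambda g: (-overlaps[g], g))


@dataclass(frozen=True)
class ChimericReadCandidate:
    """One read's evidence for an ordered fusion gene pair."""

    read_id: str
    gene5: str
    gene3: str
    break5: int
    break3: int
    dist5: int
    dist3: int
    identity5: float
    identity3: float
    seg5: AlignmentSegment
    seg3: AlignmentSegment

    def __post_init__(self) -> None:
        if self.gene5 == self.gene3:
            raise ValueError("gene5 and gene3 must differ")
        if self.dist5 < 0 or self.dist3 < 0:
            raise ValueError("boundary distances must be non-negative")


def _junction_end(seg: AlignmentSegment, side: str) -> int:
    """Genome coordinate of the segment end facing the read junction.

    ``side`` is 'downstream' for the upstream-on-read segment (junction at
    its read_end) and 'upstream' for the downstream-on-read segment.
    """
    if side == "downstream":
        return seg.genome_end if seg.align_strand == "+" else seg.genome_start
    return seg.genome_start if seg.align_strand == "+" else seg.genome_end


def derive_read_candidates(
    segments: list[AlignmentSegment],
    gms: GeneModelSet,
    index: ExonBoundaryIndex,
    config: FusionCallingConfig = DEFAULT_CONFIG,
) -> list[ChimericReadCandidate]:
    """Chimeric candidates from one read's segments (sorted by read coord).

    Consecutive segment pairs assigned to two different genes at distinct
    loci, both with identity >= ``config.min_identity``, yield one candidate
    each; a read contributes at most one candidate per gene pair. The gene
    order is flipped when both segments align antisense to their genes'
    strands (the read is then the reverse complement of the fusion
    transcript).
    """
    genes = [assign_segment_gene(s, gms) for s in segments]
    out: list[ChimericReadCandidate] = []
    seen_pairs: set[tuple[str, str]] = set()
    for a, b, ga, gb in zip(segments, segments[1:], genes, genes[1:]):
        if ga is None or gb is None or ga == gb:
            continue
        if not distinct_loci(a, b, config):
            continue
        if a.identity < config.min_identity or b.identity < config.min_identity:
            continue
        sense_a = a.align_strand == gms[ga].strand
        sense_b = b.align_strand == gms[gb].strand
        break_a = _junction_end(a, "downstream")
        break_b = _junction_end(b, "upstream")
        if not sense_a and not sense_b:
            gene5, gene3 = gb, ga
            seg5, seg3 = b, a
            break5, break3 = break_b, break_a
        else:
            gene5, gene3 = ga, gb
            seg5, seg3 = a, b
            break5, break3 = break_a, break_b
        if (gene5, gene3) in seen_pairs:
            continue
        seen_pairs.add((gene5, gene3))
        dist5, _ = index.min_distance(seg5.chrom, break5, gene_id=gene5)
        dist3, _ = index.min_distance(seg3.chrom, break3, gene_id=gene3)
        out.append(
            ChimericReadCandidate(
                read_id=a.read_id,
                gene5=gene5,
                gene3=gene3,
                break5=break5,
                break3=break3,
                dist5=dist5,
                dist3=dist3,
                identity5=seg5.identity,
                identity3=seg3.identity,
                seg5=seg5,
                seg3=seg3,
            )
        )
    return out


@dataclass
class FusionCandidate:
    """An ordered fusion gene pair with its supporting chimeric reads."""

    gene5: str
    gene3: str
    reads: list[ChimericReadCandidate] = field(default_factory=list)
    ffpm: float = 0.0
    annotations: list[str] = field(default_factory=list)

    @property
    def read_ids(self) -> list[str]:
        seen = {}
        for r in self.reads:
            seen.setdefault(r.read_id, None)
        return list(seen)

    @property
    def read_count(self) -> int:
        return len(self.read_ids)

    @property
    def name(self) -> str:
        return f"{self.gene5}--{self.gene3}"


def group_candidates(read_candidates) -> list[FusionCandidate]:
    by_pair: dict[tuple[str, str], FusionCandidate] = {}
    for rc in read_candidates:
        cand = by_pair.setdefault((rc.gene5, rc.gene3), FusionCandidate(rc.gene5, rc.gene3))
        cand.reads.append(rc)
    return list(by_pair.values())


# ---------------------------------------------------------------------------
# retention and filtering


def phase1_retention_test(
    candidate: FusionCandidate, config: FusionCallingConfig = DEFAULT_CONFIG
) -> bool:
    """Exon-boundary proximity retention rule for a candidate gene pair.

    Retained iff some read has both breakpoint-to-boundary distances within
    the strict bound (50 b), or some read has one distance within the strict
    bound and the other within the relaxed bound (1 kb) while multiple reads
    support the pair.
    """
    strict, relaxed = config.max_boundary_dist_strict, config.max_boundary_dist_relaxed
    dists = [(r.dist5, r.dist3) for r in candidate.reads]
    if any(d5 <= strict and d3 <= strict for d5, d3 in dists):
        return True
    if candidate.read_count >= config.min_reads_relaxed and any(
        min(d5, d3) <= strict and max(d5, d3) <= relaxed for d5, d3 in dists
    ):
        return True
    return False


def compute_ffpm(read_count: int, total_reads: int) -> float:
    """Fusion reads per million total reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return read_count * 1_000_000 / total_reads


def filter_candidates(
    candidates: list[FusionCandidate],
    total_reads: int,
    config: FusionCallingConfig = DEFAULT_CONFIG,
    *,
    overlapping_pairs: set | frozenset = frozenset(),
    similarity: SimilarityMap | None = None,
    excluded_pairs: set | frozenset = frozenset(),
) -> list[FusionCandidate]:
    """Annotation and expression prefilters on grouped candidates.

    Drops pairs on the user-supplied exclusion ("red herring"/normal) list,
    pairs of genes with overlapping genomic spans, paralogous pairs (when
    paralog filtering is enabled and a paralog table is present), and pairs
    below the minimum FFPM.
    """
    retained = []
    for cand in candidates:
        pair = frozenset((cand.gene5, cand.gene3))
        if pair in excluded_pairs:
            log.debug("%s dropped: on exclusion list", cand.name)
            continue
        if pair in overlapping_pairs:
            log.debug("%s dropped: overlapping gene spans", cand.name)
            continue
        if (
            config.paralog_filter
            and similarity is not None
            and similarity.is_paralog_pair(cand.gene5, cand.gene3)
        ):
            log.debug("%s dropped: paralogous gene pair", cand.name)
            continue
        cand.ffpm = compute_ffpm(cand.read_count, total_reads)
        if cand.ffpm < config.min_ffpm:
            log.debug("%s dropped: FFPM %.3g below %.3g", cand.name, cand.ffpm, config.min_ffpm)
            continue
        retained.append(cand)
    return retained


def run_phase1(
    alignments,
    gms: GeneModelSet,
    index: ExonBoundaryIndex,
    total_reads: int,
    config: FusionCallingConfig = DEFAULT_CONFIG,
    *,
    overlapping_pairs: set | frozenset | None = None,
    similarity: SimilarityMap | None = None,
    excluded_pairs: set | frozenset = frozenset(),
) -> list[FusionCandidate]:
    """Full phase-1 scan: chimeric reads -> retained fusion candidates."""
    from .annotation import overlapping_gene_pairs

    if overlapping_pairs is None:
        overlapping_pairs = overlapping_gene_pairs(gms)
    chimeric = collect_chimeric_reads(alignments, config)
    read_cands = []
    for segs in chimeric.values():
        read_cands.extend(derive_read_candidates(segs, gms, index, config))
    candidates = [c for c in group_candidates(read_cands) if phase1_retention_test(c, config)]
    return filter_candidates(
        candidates,
        total_reads,
        config,
        overlapping_pairs=overlapping_pairs,
        similarity=similarity,
        excluded_pairs=excluded_pairs,
    )


def write_candidate_table(candidates: list[FusionCandidate], path) -> None:
    """Phase-1 candidate TSV: gene5, gene3, n_reads, ffpm, read_ids."""
    with open(path, "w") as fh:
        fh.write("gene5\tgene3\tn_reads\tffpm\tread_ids\n")
        for c in sorted(candidates, key=lambda c: (-c.read_count, c.name)):
            fh.write(f"{c.gene5}\t{c.gene3}\t{c.read_count}\t{c.ffpm:.4f}\t{','.join(c.read_ids)}\n")
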