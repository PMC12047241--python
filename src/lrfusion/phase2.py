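"""Phase 2: realignment to fusion contigs, breakpoint tallying, and reporting.

Candidate reads are realigned to each fusion contig (via an external
minimap2 adapter or the built-in projection realigner that replays phase-1
genomic placements), alignment ends within 3 bases of an exon boundary are
snapped onto it, fusion-supporting reads are required to anchor at least
25 exonic bases in each gene (excluding exon regions flagged as similar
between the pair), breakpoints are tallied per read-supported junction,
splice dinucleotides classified (GT..AG consensus by default), final FFPM /
read-support / isoform-fraction filters applied, and a tab-delimited fusion
report written.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam

from .annotation import SimilarityMap
from .config import DEFAULT_CONFIG, FusionCallingConfig
from .fusion_contig import FusionContig
from .phase1 import ChimericReadCandidate, FusionCandidate, compute_ffpm

log = logging.getLogger(__name__)

Block = tuple[int, int, int, int]  # contig start, contig end, read start, read end

REPORT_COLUMNS = [
    "#FusionName",
    "LeftGene",
    "LeftBreakpoint",
    "RightGene",
    "RightBreakpoint",
    "NumLongReads",
    "LR_FFPM",
    "SpliceType",
    "Annotations",
    "LongReadIds",
]

SPLICE_CONSENSUS = "consensus"
SPLICE_NON_CONSENSUS = "non_consensus"


@dataclass
class ContigAlignment:
    """A read's alignment to one fusion contig as sorted blocks."""

    read_id: str
    blocks: list[Block]

    def __post_init__(self) -> None:
        self.blocks.sort(key=lambda b: (b[0], b[1]))


class RealignmentError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# realignment adapters


class ProjectionRealigner:
    """Replay phase-1 genomic placements onto contig coordinates.

    Each supporting read's two gene segments are intersected with the
    assigned gene's merged exons and projected through the contig coordinate
    map, producing the alignment an ideal splice-aware realignment would
    yield. Deterministic, with no external process.
    """

    def __init__(self, gms) -> None:
        self.gms = gms

    def align(self, contig: FusionContig, candidate: FusionCandidate, reads=None):
        out = []
        for rc in candidate.reads:
            blocks = self._project_read(contig, rc)
            if blocks:
                out.append(ContigAlignment(rc.read_id, blocks))
        return out

    def _project_read(self, contig: FusionContig, rc: ChimericReadCandidate) -> list[Block]:
        blocks: list[tuple[int, int]] = []
        for gid, seg in ((rc.gene5, rc.seg5), (rc.gene3, rc.seg3)):
            gene = self.gms[gid]
            for es, ee in gene.merged_exons:
                s, e = max(es, seg.genome_start), min(ee, seg.genome_end)
                if s < e:
                    blocks.extend(contig.map_genome_interval(seg.chrom, s, e))
        blocks.sort()
        out: list[Block] = []
        rpos = 0
        for cs, ce in blocks:
            out.append((cs, ce, rpos, rpos + (ce - cs)))
            rpos += ce - cs
        return out


class Minimap2Realigner:
    """Shell out to minimap2 for splice-aware realignment to contigs."""

    def __init__(self, preset: str = "splice", executable: str = "minimap2", extra_args=()):
        self.preset = preset
        self.executable = executable
        self.extra_args = list(extra_args)

    def align(self, contig: FusionContig, candidate: FusionCandidate, reads=None):
        if reads is None:
            raise RealignmentError(f"{contig.contig_id}: read sequences required for minimap2")
        if shutil.which(self.executable) is None:
            raise RealignmentError(f"{self.executable} not found on PATH")
        wanted = set(candidate.read_ids)
        with tempfile.TemporaryDirectory(prefix="lrfusion_mm2_") as tmp:
            ref = Path(tmp) / "contig.fa"
            fq = Path(tmp) / "reads.fa"
            ref.write_text(f">{contig.contig_id}\n{contig.sequence}\n")
            with open(fq, "w") as fh:
                for name in wanted:
                    if name in reads:
                        fh.write(f">{name}\n{reads[name]}\n")
            cmd = [self.executable, "-ax", self.preset, *self.extra_args, str(ref), str(fq)]
            try:
                proc = subprocess.run(cmd, capture_output=True, text=True, check=True)
            except subprocess.CalledProcessError as exc:
                raise RealignmentError(
                    f"{contig.contig_id}: minimap2 failed: {exc.stderr.strip()}"
                ) from exc
            return _parse_contig_sam(proc.stdout)


def _parse_contig_sam(sam_text: str) -> list[ContigAlignment]:
    """Best (primary) alignment per read, blocks split at introns/indels."""
    best: dict[str, ContigAlignment] = {}
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
        fh.write(sam_text)
        tmp_path = fh.name
    try:
        with pysam.AlignmentFile(tmp_path, "r", check_sq=False) as fh:
            for a in fh:
                if a.is_unmapped or a.is_secondary or a.is_supplementary:
                    continue
                blocks: list[Block] = []
                c, r = a.reference_start, a.query_alignment_start
                for op, length in a.cigartuples:
                    if op in (0, 7, 8):  # M, =, X
                        blocks.append((c, c + length, r, r + length))
                        c += length
                        r += length
                    elif op == 1:  # I
                        r += length
                    elif op in (2, 3):  # D, N
                        c += length
                best[a.query_name] = ContigAlignment(a.query_name, blocks)
    finally:
        Path(tmp_path).unlink(missing_ok=True)
    return list(best.values())


# ---------------------------------------------------------------------------
# snapping and classification


def snap_alignment_ends(
    aln: ContigAlignment, boundaries, snap_dist: int = DEFAULT_CONFIG.snap_dist
) -> ContigAlignment:
    """Snap block ends within ``snap_dist`` bases of an exon boundary onto it.

    Ends already on a boundary are unchanged; ends further than the
    tolerance are unchanged; snapping never reorders blocks. Idempotent.
    """
    boundaries = sorted(boundaries)
    if not boundaries:
        return aln

    def _snap(pos: int) -> int:
        import bisect

        i = bisect.bisect_left(boundaries, pos)
        cands = []
        if i > 0:
            cands.append(boundaries[i - 1])
        if i < len(boundaries):
            cands.append(boundaries[i])
        nearest = min(cands, key=lambda b: (abs(b - pos), b))
        return nearest if abs(nearest - pos) <= snap_dist else pos

    new_blocks: list[Block] = []
    for cs, ce, rs, re in aln.blocks:
        ns, ne = _snap(cs), _snap(ce)
        if ns >= ne:  # refuse snaps that would collapse the block
            ns, ne = cs, ce
        new_blocks.append((ns, ne, rs, re))
    return ContigAlignment(aln.read_id, new_blocks)


def _overlap(blocks, regions) -> int:
    total = 0
    for cs, ce, *_ in blocks:
        for s, e in regions:
            total += max(0, min(ce, e) - max(cs, s))
    return total


def classify_fusion_read(
    aln: ContigAlignment,
    contig: FusionContig,
    similarity: SimilarityMap | None = None,
    config: FusionCallingConfig = DEFAULT_CONFIG,
):
    """Decide whether a contig alignment is fusion evidence.

    Evidence requires >= ``min_per_side_exon_bp`` cumulative exonic overlap
    within each gene's contig blocks, not counting exon regions flagged as
    sequence-similar between the two genes. Returns (is_evidence,
    (contig_break5, contig_break3) or None).
    """
    g5_blocks = [b for b in aln.blocks if contig.gene_of_block(b[0], b[1]) == contig.gene5]
    g3_blocks = [b for b in aln.blocks if contig.gene_of_block(b[0], b[1]) == contig.gene3]
    if not g5_blocks or not g3_blocks:
        return False, None

    eff = {}
    for gid, blocks, partner in (
        (contig.gene5, g5_blocks, contig.gene3),
        (contig.gene3, g3_blocks, contig.gene5),
    ):
        exonic = _overlap(blocks, contig.exon_blocks[gid])
        if similarity is not None and similarity:
            sim_contig: list[tuple[int, int]] = []
            for chrom, s, e in similarity.similar_regions_of(gid, partner):
                sim_contig.extend(contig.map_genome_interval(chrom, s, e))
            exonic -= _overlap(blocks, sim_contig)
        eff[gid] = exonic

    if eff[contig.gene5] < config.min_per_side_exon_bp:
        return False, None
    if eff[contig.gene3] < config.min_per_side_exon_bp:
        return False, None
    break5 = g5_blocks[-1][1]
    break3 = g3_blocks[0][0]
    return True, (break5, break3)


def classify_splice(
    sequence: str,
    contig_break5: int,
    contig_break3: int,
    consensus_set=DEFAULT_CONFIG.consensus_dinucleotides,
):
    """Splice dinucleotides flanking a contig breakpoint pair.

    Donor = the two bases immediately 3' of the 5'-gene break; acceptor =
    the two bases immediately 5' of the 3'-gene break. Breakpoints at the
    contig edge are non-consensus with an edge flag.
    """
    edge = contig_break5 + 2 > len(sequence) or contig_break3 - 2 < 0
    donor = sequence[contig_break5 : contig_break5 + 2].upper()
    acceptor = sequence[max(0, contig_break3 - 2) : contig_break3].upper()
    if edge or len(donor) < 2 or len(acceptor) < 2:
        return donor, acceptor, SPLICE_NON_CONSENSUS, True
    cls = SPLICE_CONSENSUS if (donor, acceptor) in consensus_set else SPLICE_NON_CONSENSUS
    return donor, acceptor, cls, False


# ---------------------------------------------------------------------------
# breakpoint tallies and filtering


@dataclass
class BreakpointEvidence:
    """Read support tallied at one exact (post-snap) contig breakpoint pair."""

    gene5: str
    gene3: str
    contig_break5: int
    contig_break3: int
    left_breakpoint: str
    right_breakpoint: str
    donor: str
    acceptor: str
    splice_class: str
    read_ids: list[str]
    ffpm: float
    at_contig_edge: bool = False
    annotations: list[str] = field(default_factory=list)

    @property
    def read_count(self) -> int:
        return len(self.read_ids)

    @property
    def fusion_name(self) -> str:
        return f"{self.gene5}--{self.gene3}"


def tally_breakpoints(
    evidence_reads,
    contig: FusionContig,
    total_reads: int,
    config: FusionCallingConfig = DEFAULT_CONFIG,
) -> list[BreakpointEvidence]:
    """Group fusion-supporting reads by exact breakpoint pair.

    ``evidence_reads`` is an iterable of (read_id, (contig_break5,
    contig_break3)). Genomic breakpoints and splice classes are attached.
    """
    groups: dict[tuple[int, int], list[str]] = {}
    for read_id, bp in evidence_reads:
        groups.setdefault(bp, []).append(read_id)
    out = []
    for (c5, c3), read_ids in sorted(groups.items()):
        unique_reads = list(dict.fromkeys(read_ids))
        donor, acceptor, cls, edge = classify_splice(
            contig.sequence, c5, c3, config.consensus_dinucleotides
        )
        out.append(
            BreakpointEvidence(
                gene5=contig.gene5,
                gene3=contig.gene3,
                contig_break5=c5,
                contig_break3=c3,
                left_breakpoint=contig.left_breakpoint(c5),
                right_breakpoint=contig.right_breakpoint(c3),
                donor=donor,
                acceptor=acceptor,
                splice_class=cls,
                read_ids=unique_reads,
                ffpm=compute_ffpm(len(unique_reads), total_reads),
                at_contig_edge=edge,
            )
        )
    return out


def apply_final_filters(
    evidences: list[BreakpointEvidence], config: FusionCallingConfig = DEFAULT_CONFIG
) -> list[BreakpointEvidence]:
    """Per-breakpoint FFPM, splice-class read-support, and isoform filters.

    The dominant-isoform count is taken over all tallied breakpoints of a
    fusion pair (before the other filters) so every filter is monotone in
    its threshold. Isoforms with a read count below ``isoform_frac`` of the
    dominant count are discarded as noise.
    """
    by_fusion: dict[str, list[BreakpointEvidence]] = {}
    for ev in evidences:
        by_fusion.setdefault(ev.fusion_name, []).append(ev)
    out = []
    for evs in by_fusion.values():
        dominant = max(ev.read_count for ev in evs)
        for ev in evs:
            if ev.ffpm < config.min_ffpm:
                continue
            if ev.splice_class == SPLICE_NON_CONSENSUS and ev.read_count < config.min_reads_nonconsensus:
                continue
            if ev.splice_class == SPLICE_CONSENSUS and ev.read_count < 1:
                continue
            if ev.read_count < config.isoform_frac * dominant:
                continue
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# report


@dataclass
class FusionReportRow:
    fusion_name: str
    left_gene: str
    left_breakpoint: str
    right_gene: str
    right_breakpoint: str
    n_long_reads: int
    ffpm: float
    splice_type: str
    annotations: str
    read_ids: list[str]
    cell_barcodes: list[str] | None = None


def build_report_rows(evidences: list[BreakpointEvidence], single_cell: bool = False):
    """Report rows, sorted by descending read support then fusion name."""
    rows = []
    for ev in evidences:
        barcodes = None
        if single_cell:
            from .single_cell import parse_tagged_read_name

            barcodes = sorted({parse_tagged_read_name(r).barcode for r in ev.read_ids})
        rows.append(
            FusionReportRow(
                fusion_name=ev.fusion_name,
                left_gene=ev.gene5,
                left_breakpoint=ev.left_breakpoint,
                right_gene=ev.gene3,
                right_breakpoint=ev.right_breakpoint,
                n_long_reads=ev.read_count,
                ffpm=ev.ffpm,
                splice_type=(
                    "ONLY_REF_SPLICE" if ev.splice_class == SPLICE_CONSENSUS else "INCL_NON_REF_SPLICE"
                ),
                annotations=",".join(ev.annotations) if ev.annotations else ".",
                read_ids=ev.read_ids,
                cell_barcodes=barcodes,
            )
        )
    rows.sort(key=lambda r: (-r.n_long_reads, r.fusion_name, r.left_breakpoint, r.right_breakpoint))
    return rows


def write_fusion_report(rows, path, single_cell: bool = False) -> None:
    """Write the tab-delimited fusion report (header always present)."""
    cols = list(REPORT_COLUMNS) + (["CellBarcodes"] if single_cell else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fields = [
                r.fusion_name,
                r.left_gene,
                r.left_breakpoint,
                r.right_gene,
                r.right_breakpoint,
                str(r.n_long_reads),
                f"{r.ffpm:.6g}",
                r.splice_type,
                r.annotations,
                ",".join(r.read_ids),
            ]
            if single_cell:
                fields.append(",".join(r.cell_barcodes or []))
            fh.write("\t".join(fields) + "\n")


def read_fusion_report(path) -> pd.DataFrame:
    """Round-trip reader for the fusion report TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"LongReadIds": str})
    if "#FusionName" not in df.columns:
        raise ValueError(f"{path}: not a fusion report (missing #FusionName column)")
    return df
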