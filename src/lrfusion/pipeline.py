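"""End-to-end fusion calling: phase-1 scan -> contigs -> phase-2 report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import (
    ExonBoundaryIndex,
    GeneModelSet,
    SimilarityMap,
    overlapping_gene_pairs,
    parse_gene_models,
)
from .config import DEFAULT_CONFIG, FusionCallingConfig
from .fusion_contig import FusionContig, build_fusion_contig
from .phase1 import FusionCandidate, run_phase1
from .phase2 import (
    BreakpointEvidence,
    FusionReportRow,
    ProjectionRealigner,
    apply_final_filters,
    build_report_rows,
    classify_fusion_read,
    snap_alignment_ends,
    tally_breakpoints,
    write_fusion_report,
)

log = logging.getLogger(__name__)


@dataclass
class FusionCallResult:
    rows: list[FusionReportRow]
    evidences: list[BreakpointEvidence]
    candidates: list[FusionCandidate]
    contigs: dict[str, FusionContig] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "#FusionName": r.fusion_name,
                    "LeftGene": r.left_gene,
                    "LeftBreakpoint": r.left_breakpoint,
                    "RightGene": r.right_gene,
                    "RightBreakpoint": r.right_breakpoint,
                    "NumLongReads": r.n_long_reads,
                    "LR_FFPM": r.ffpm,
                    "SpliceType": r.splice_type,
                    "Annotations": r.annotations,
                    "LongReadIds": ",".join(r.read_ids),
                }
                for r in self.rows
            ]
        )


def call_fusions(
    gene_models,
    genome,
    alignments,
    total_reads: int,
    config: FusionCallingConfig = DEFAULT_CONFIG,
    *,
    similarity: SimilarityMap | None = None,
    excluded_pairs: set | frozenset = frozenset(),
    realigner=None,
    reads: dict[str, str] | None = None,
    single_cell: bool = False,
) -> FusionCallResult:
    """Run both phases and produce the fusion report rows.

    ``gene_models`` is a :class:`GeneModelSet` or a GTF path; ``genome`` a
    dict of chromosome sequences or a pyfaidx.Fasta; ``alignments`` an
    iterable of segments or a PAF/SAM path; ``total_reads`` the number of
    input reads the sample was sequenced to (the FFPM denominator). The
    default realigner replays phase-1 placements onto the contigs; pass a
    :class:`~lrfusion.phase2.Minimap2Realigner` plus ``reads`` (id ->
    sequence) for true realignment.
    """
    gms = gene_models if isinstance(gene_models, GeneModelSet) else parse_gene_models(gene_models)
    index = ExonBoundaryIndex.from_gene_models(gms)
    overlap_pairs = overlapping_gene_pairs(gms)

    candidates = run_phase1(
        alignments,
        gms,
        index,
        total_reads,
        config,
        overlapping_pairs=overlap_pairs,
        similarity=similarity,
        excluded_pairs=excluded_pairs,
    )

    realigner = realigner if realigner is not None else ProjectionRealigner(gms)
    contigs: dict[str, FusionContig] = {}
    evidences: list[BreakpointEvidence] = []
    for cand in candidates:
        contig = build_fusion_contig(cand.gene5, cand.gene3, gms, genome, config)
        contigs[contig.contig_id] = contig
        alns = realigner.align(contig, cand, reads)
        boundaries = contig.exon_boundaries()
        evidence_reads = []
        for aln in alns:
            snapped = snap_alignment_ends(aln, boundaries, config.snap_dist)
            is_evidence, bp = classify_fusion_read(snapped, contig, similarity, config)
            if is_evidence:
                evidence_reads.append((snapped.read_id, bp))
        evidences.extend(tally_breakpoints(evidence_reads, contig, total_reads, config))

    retained = apply_final_filters(evidences, config)
    rows = build_report_rows(retained, single_cell=single_cell)
    return FusionCallResult(rows=rows, evidences=retained, candidates=candidates, contigs=contigs)


def call_fusions_to_dir(result: FusionCallResult, outdir, single_cell: bool = False) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = outdir / "fusion_report.tsv"
    write_fusion_report(result.rows, report, single_cell=single_cell)
    return report
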