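"""Phase-2 fusion contig modelling.

Each retained candidate gene pair is modelled as a single artificial contig:
the 5' gene followed by the 3' gene, both reading 5'->3' (minus-strand genes
reverse-complemented), with introns longer than 1 kb shrunk to their first
and last 500 bases and a run of N separating the two genes. An exact
bidirectional contig<->genome coordinate map supports reporting genomic
breakpoints from contig alignments.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .annotation import GeneModelSet
from .config import DEFAULT_CONFIG, FusionCallingConfig

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Extract genome sequence; works for dict-of-str and pyfaidx.Fasta."""
    return str(genome[chrom][start:end]).upper()


@dataclass(frozen=True)
class MapInterval:
    """Affine mapping between a contig interval and a genome interval.

    For strand '-', contig position c maps to genome position
    ``genome_end - 1 - (c - contig_start)``.
    """

    contig_start: int
    contig_end: int
    chrom: str | None  # None for the unmapped spacer
    genome_start: int
    genome_end: int
    strand: str
    kind: str  # 'exon' | 'intron' | 'spacer'
    gene: str | None


class FusionContig:
    """Modeled contig for one ordered fusion gene pair."""

    def __init__(
        self,
        gene5: str,
        gene3: str,
        sequence: str,
        intervals: list[MapInterval],
        exon_blocks: dict[str, list[tuple[int, int]]],
        gene5_end: int,
        gene3_start: int,
        strands: dict[str, str],
    ) -> None:
        self.gene5 = gene5
        self.gene3 = gene3
        self.sequence = sequence
        self.intervals = intervals
        self.exon_blocks = exon_blocks
        self.gene5_end = gene5_end
        self.gene3_start = gene3_start
        self.strands = strands
        self._starts = [iv.contig_start for iv in intervals]

    @property
    def contig_id(self) -> str:
        return f"{self.gene5}--{self.gene3}"

    def __len__(self) -> int:
        return len(self.sequence)

    # -- coordinate mapping -------------------------------------------------

    def _interval_at(self, pos: int) -> MapInterval:
        if not 0 <= pos < len(self.sequence):
            raise ValueError(f"{self.contig_id}: position {pos} outside contig [0, {len(self)})")
        i = bisect.bisect_right(self._starts, pos) - 1
        return self.intervals[i]

    def contig_to_genome(self, pos: int):
        """Map a contig position to (chrom, genome_pos, strand); spacer -> None."""
        iv = self._interval_at(pos)
        if iv.chrom is None:
            return None
        off = pos - iv.contig_start
        if iv.strand == "+":
            return iv.chrom, iv.genome_start + off, iv.strand
        return iv.chrom, iv.genome_end - 1 - off, iv.strand

    def genome_to_contig(self, chrom: str, pos: int):
        """Map a genome position onto the contig; bases dropped by intron
        shrinking (or outside both genes) return None."""
        for iv in self.intervals:
            if iv.chrom != chrom or not iv.genome_start <= pos < iv.genome_end:
                continue
            if iv.strand == "+":
                return iv.contig_start + (pos - iv.genome_start)
            return iv.contig_start + (iv.genome_end - 1 - pos)
        return None

    def map_genome_interval(self, chrom: str, start: int, end: int, kinds=("exon",)):
        """Contig intervals covered by genomic [start, end), restricted to
        interval kinds (exon blocks by default). Returns sorted, half-open
        contig intervals."""
        pieces = []
        for iv in self.intervals:
            if iv.chrom != chrom or iv.kind not in kinds:
                continue
            s, e = max(start, iv.genome_start), min(end, iv.genome_end)
            if s >= e:
                continue
            if iv.strand == "+":
                pieces.append((iv.contig_start + s - iv.genome_start, iv.contig_start + e - iv.genome_start))
            else:
                pieces.append((iv.contig_start + iv.genome_end - e, iv.contig_start + iv.genome_end - s))
        return sorted(pieces)

    def exon_boundaries(self) -> list[int]:
        out = sorted({b for blocks in self.exon_blocks.values() for s, e in blocks for b in (s, e)})
        return out

    def gene_of_block(self, c_start: int, c_end: int) -> str | None:
        mid = (c_start + c_end) // 2
        if mid < self.gene5_end:
            return self.gene5
        if mid >= self.gene3_start:
            return self.gene3
        return None

    # -- breakpoint display -------------------------------------------------

    def left_breakpoint(self, contig_break5: int) -> str:
        """1-based genomic string for the last aligned base of the 5' gene."""
        mapped = self.contig_to_genome(contig_break5 - 1)
        if mapped is None:
            return f"{self.contig_id}:{contig_break5}:."
        chrom, gpos, strand = mapped
        return f"{chrom}:{gpos + 1}:{strand}"

    def right_breakpoint(self, contig_break3: int) -> str:
        """1-based genomic string for the first aligned base of the 3' gene."""
        mapped = self.contig_to_genome(contig_break3)
        if mapped is None:
            return f"{self.contig_id}:{contig_break3}:."
        chrom, gpos, strand = mapped
        return f"{chrom}:{gpos + 1}:{strand}"


def map_coordinate(contig: FusionContig, position: int, direction: str, chrom: str | None = None):
    """Exact coordinate mapping in either direction.

    ``direction`` is 'contig_to_genome' or 'genome_to_contig' (the latter
    needs ``chrom``). Unmapped positions (shrunk intron middles, spacer)
    return None.
    """
    if direction == "contig_to_genome":
        return contig.contig_to_genome(position)
    if direction == "genome_to_contig":
        if chrom is None:
            raise ValueError("genome_to_contig mapping requires chrom")
        return contig.genome_to_contig(chrom, position)
    raise ValueError(f"unknown direction {direction!r}")


def _gene_pieces(gene, config: FusionCallingConfig):
    """Genomic (start, end, kind) pieces of one gene: merged exons plus
    verbatim or flank-shrunk introns, in ascending genomic order."""
    exons = gene.merged_exons
    pieces: list[tuple[int, int, str]] = []
    for i, (s, e) in enumerate(exons):
        if i > 0:
            prev_end = exons[i - 1][1]
            intron_len = s - prev_end
            if intron_len <= config.intron_cap:
                if intron_len > 0:
                    pieces.append((prev_end, s, "intron"))
            else:
                pieces.append((prev_end, prev_end + config.intron_flank, "intron"))
                pieces.append((s - config.intron_flank, s, "intron"))
        pieces.append((s, e, "exon"))
    return pieces


def build_fusion_contig(
    gene5: str,
    gene3: str,
    gms: GeneModelSet,
    genome,
    config: FusionCallingConfig = DEFAULT_CONFIG,
) -> FusionContig:
    """Construct the fusion contig for an ordered gene pair.

    Uses the collapsed (all-transcript exon union) model of each gene so
    that any isoform's reads can realign. Raises KeyError for unknown genes.
    """
    seq_parts: list[str] = []
    intervals: list[MapInterval] = []
    exon_blocks: dict[str, list[tuple[int, int]]] = {gene5: [], gene3: []}
    strands: dict[str, str] = {}
    cpos = 0
    gene5_end = 0
    gene3_start = 0

    for which, gid in (("five", gene5), ("three", gene3)):
        gene = gms[gid]
        strands[gid] = gene.strand
        pieces = _gene_pieces(gene, config)
        if gene.strand == "-":
            pieces = pieces[::-1]
        for gs, ge, kind in pieces:
            frag = fetch_sequence(genome, gene.chrom, gs, ge)
            if gene.strand == "-":
                frag = reverse_complement(frag)
            intervals.append(
                MapInterval(cpos, cpos + len(frag), gene.chrom, gs, ge, gene.strand, kind, gid)
            )
            if kind == "exon":
                exon_blocks[gid].append((cpos, cpos + len(frag)))
            seq_parts.append(frag)
            cpos += len(frag)
        if which == "five":
            gene5_end = cpos
            intervals.append(
                MapInterval(cpos, cpos + config.spacer_len, None, 0, 0, ".", "spacer", None)
            )
            seq_parts.append("N" * config.spacer_len)
            cpos += config.spacer_len
            gene3_start = cpos

    return FusionContig(
        gene5=gene5,
        gene3=gene3,
        sequence="".join(seq_parts),
        intervals=intervals,
        exon_blocks=exon_blocks,
        gene5_end=gene5_end,
        gene3_start=gene3_start,
        strands=strands,
    )


def write_contigs_fasta(contigs, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.contig_id}\n")
            for i in range(0, len(contig.sequence), width):
                fh.write(contig.sequence[i : i + width] + "\n")


def write_block_table(contigs, path) -> None:
    """BED-like table of contig blocks and their genomic sources."""
    with open(path, "w") as fh:
        fh.write("contig\tcontig_start\tcontig_end\tkind\tgene\tchrom\tgenome_start\tgenome_end\tstrand\n")
        for contig in contigs:
            for iv in contig.intervals:
                fh.write(
                    f"{contig.contig_id}\t{iv.contig_start}\t{iv.contig_end}\t{iv.kind}\t"
                    f"{iv.gene or '.'}\t{iv.chrom or '.'}\t{iv.genome_start}\t{iv.genome_end}\t{iv.strand}\n"
                )
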