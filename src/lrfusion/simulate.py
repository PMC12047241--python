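"""Seeded synthetic fusion-transcriptome fixtures at desk scale.

Generates a toy genome with multi-exon genes (GT..AG intron flanks on the
coding strand), fusion transcripts joined at internal exon junctions so
every truth breakpoint is a consensus splice site by construction,
background (non-fusion) transcript reads, long reads with i.i.d. per-base
substitution/insertion/deletion error and optional 3'-anchored truncation,
ideal pre-error alignments in genome coordinates (so error degrades
identity, not placement), and truth tables in the benchmarking dialect.
Everything is byte-deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .annotation import GeneModel, GeneModelSet, write_gene_models
from .fusion_contig import reverse_complement
from .phase1 import AlignmentSegment, write_paf

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FusionPlan:
    """One planned fusion: genes, junction exon indices (transcript order,
    0-based), and the number of supporting reads to simulate."""

    gene5: str
    gene3: str
    donor_exon: int
    acceptor_exon: int
    n_reads: int

    @property
    def name(self) -> str:
        return f"{self.gene5}--{self.gene3}"

    @property
    def transcript_id(self) -> str:
        return f"{self.gene5}--{self.gene3}|{self.donor_exon}.{self.acceptor_exon}"


@dataclass
class SimSpec:
    """Study conditions for one synthetic data set."""

    seed: int = 0
    n_genes: int = 20
    genes_per_chrom: int = 5
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (100, 2000)
    intergenic_gap: int = 120_000  # > the 100 kb locus-separation cutoff
    minus_strand_prob: float = 0.4
    fusions: list[FusionPlan] | None = None
    n_fusions: int = 5
    fusion_reads: tuple[int, int] = (3, 8)
    background_reads_per_gene: int = 10
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    truncation_prob: float = 0.0
    min_retained_frac: float = 0.5
    # single-cell plan: fusion name -> {barcode -> UMI count}
    single_cell: dict[str, dict[str, int]] | None = None

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.ins_rate, self.del_rate, self.truncation_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.exons_per_gene[0] < 2:
            raise ValueError("genes need >= 2 exons so fusions can use internal junctions")


@dataclass(frozen=True)
class TranscriptPiece:
    """One exon's contribution to a transcript (transcript coords + source)."""

    t_start: int
    t_end: int
    gene: str
    chrom: str
    g_start: int
    g_end: int
    strand: str


@dataclass
class SimRead:
    name: str
    seq: str
    segments: list[AlignmentSegment]
    fusion_name: str | None  # None for background reads


@dataclass
class SimulatedFusion:
    plan: FusionPlan
    layout: list[TranscriptPiece]
    sequence: str
    breakpoint5: str  # chrom:pos (1-based)
    breakpoint3: str


# ---------------------------------------------------------------------------
# genome and annotation


def _random_seq_array(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def generate_genome_and_annotation(spec: SimSpec, rng: np.random.Generator):
    """Toy genome and gene models per the spec's layout parameters.

    Genes are placed non-overlapping with ``intergenic_gap`` between them so
    that any two genes form distinct genomic loci; introns carry GT..AG
    flanks on the coding strand (their genomic reverse complement on minus
    strand genes).
    """
    n_chroms = -(-spec.n_genes // spec.genes_per_chrom)
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    gene_no = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = spec.intergenic_gap
        placements = []  # (gene_id, strand, exons, introns)
        while gene_no < spec.n_genes and len(placements) < spec.genes_per_chrom:
            gene_no += 1
            gid = f"GENE{gene_no:02d}"
            n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
            ex_lens = rng.integers(spec.exon_len[0], spec.exon_len[1] + 1, size=n_ex)
            in_lens = rng.integers(spec.intron_len[0], spec.intron_len[1] + 1, size=n_ex - 1)
            strand = "-" if rng.random() < spec.minus_strand_prob else "+"
            exons = []
            pos = cursor
            for i, el in enumerate(ex_lens):
                exons.append((pos, pos + int(el)))
                pos += int(el)
                if i < n_ex - 1:
                    pos += int(in_lens[i])
            placements.append((gid, strand, exons))
            cursor = pos + spec.intergenic_gap
        arr = _random_seq_array(rng, cursor)
        for gid, strand, exons in placements:
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if strand == "+":  # coding-strand intron reads GT..AG
                    arr[e1 : e1 + 2] = np.frombuffer(b"GT", dtype=np.uint8)
                    arr[s2 - 2 : s2] = np.frombuffer(b"AG", dtype=np.uint8)
                else:  # genomic reverse complement: CT..AC
                    arr[e1 : e1 + 2] = np.frombuffer(b"CT", dtype=np.uint8)
                    arr[s2 - 2 : s2] = np.frombuffer(b"AC", dtype=np.uint8)
            models.append(
                GeneModel(gid, gid, chrom, strand, {f"{gid}.t1": list(exons)})
            )
        genome[chrom] = arr.tobytes().decode()
    return genome, GeneModelSet(models)


# ---------------------------------------------------------------------------
# transcripts


def transcript_layout(gene: GeneModel, tx_id: str | None = None) -> list[TranscriptPiece]:
    """Exon pieces of one transcript in transcript (5'->3') order."""
    if tx_id is None:
        tx_id = next(iter(gene.transcripts))
    exons = gene.transcripts[tx_id]
    ordered = exons if gene.strand == "+" else exons[::-1]
    pieces, t = [], 0
    for gs, ge in ordered:
        pieces.append(TranscriptPiece(t, t + ge - gs, gene.gene_id, gene.chrom, gs, ge, gene.strand))
        t += ge - gs
    return pieces


def _shift_layout(pieces: list[TranscriptPiece]) -> list[TranscriptPiece]:
    out, t = [], 0
    for p in pieces:
        length = p.t_end - p.t_start
        out.append(TranscriptPiece(t, t + length, p.gene, p.chrom, p.g_start, p.g_end, p.strand))
        t += length
    return out


def layout_sequence(layout: list[TranscriptPiece], genome) -> str:
    parts = []
    for p in layout:
        frag = str(genome[p.chrom][p.g_start : p.g_end]).upper()
        parts.append(reverse_complement(frag) if p.strand == "-" else frag)
    return "".join(parts)


def _exon_edge_breakpoints(donor: TranscriptPiece, acceptor: TranscriptPiece):
    """1-based genomic breakpoint strings at the fused exon edges."""
    bp5 = donor.g_end if donor.strand == "+" else donor.g_start + 1
    bp3 = acceptor.g_start + 1 if acceptor.strand == "+" else acceptor.g_end
    return f"{donor.chrom}:{bp5}", f"{acceptor.chrom}:{bp3}"


def construct_fusion_transcript(
    gms: GeneModelSet, genome, plan: FusionPlan
) -> SimulatedFusion:
    """Fusion transcript: 5' gene exons 1..donor + 3' gene exons acceptor..last,
    spliced; truth breakpoints are the donor exon end and acceptor exon start
    in transcript orientation."""
    lay5 = transcript_layout(gms[plan.gene5])
    lay3 = transcript_layout(gms[plan.gene3])
    if not 0 <= plan.donor_exon < len(lay5):
        raise ValueError(f"{plan.name}: donor exon index {plan.donor_exon} out of range")
    if not 0 <= plan.acceptor_exon < len(lay3):
        raise ValueError(f"{plan.name}: acceptor exon index {plan.acceptor_exon} out of range")
    layout = _shift_layout(lay5[: plan.donor_exon + 1] + lay3[plan.acceptor_exon :])
    bp5, bp3 = _exon_edge_breakpoints(lay5[plan.donor_exon], lay3[plan.acceptor_exon])
    return SimulatedFusion(plan, layout, layout_sequence(layout, genome), bp5, bp3)


# ---------------------------------------------------------------------------
# reads with errors


def apply_errors(seq: str, rng: np.random.Generator, sub: float, ins: float, dele: float):
    """i.i.d. per-base errors; returns the read plus per-base bookkeeping.

    ``cum[i]`` is the read coordinate of template base i; ``substituted``/
    ``deleted``/``inserted`` flag each template base.
    """
    n = len(seq)
    deleted = rng.random(n) < dele if dele > 0 else np.zeros(n, dtype=bool)
    substituted = (~deleted) & (rng.random(n) < sub) if sub > 0 else np.zeros(n, dtype=bool)
    inserted = rng.random(n) < ins if ins > 0 else np.zeros(n, dtype=bool)
    out_len = (~deleted).astype(np.int64) + inserted
    cum = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(out_len, out=cum[1:])
    if not (deleted.any() or substituted.any() or inserted.any()):
        return seq, cum, substituted, deleted, inserted
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = {b: i for i, b in enumerate(_BASES)}
    parts = []
    sub_shift = rng.integers(1, 4, size=int(substituted.sum()))
    ins_base = _random_seq_array(rng, int(inserted.sum()))
    si = ii = 0
    for i in range(n):
        if not deleted[i]:
            if substituted[i]:
                idx = lut.get(arr[i], 0)
                parts.append(chr(_BASES[(idx + sub_shift[si]) % 4]))
                si += 1
            else:
                parts.append(chr(arr[i]))
        if inserted[i]:
            parts.append(chr(ins_base[ii]))
            ii += 1
    return "".join(parts), cum, substituted, deleted, inserted


def _read_segments(
    name: str,
    layout: list[TranscriptPiece],
    keep_from: int,
    cum: np.ndarray,
    substituted: np.ndarray,
    deleted: np.ndarray,
    inserted: np.ndarray,
):
    """Planned per-gene alignment segments for a (possibly truncated) read.

    The genome span of each segment covers the involved exons (introns
    included, as a splice-aware genomic alignment would report); identity
    reflects the errors placed within the segment's exonic bases.
    """
    total = layout[-1].t_end
    # group consecutive pieces by gene, intersected with [keep_from, total)
    groups: list[list[TranscriptPiece]] = []
    for p in layout:
        if p.t_end <= keep_from:
            continue
        if groups and groups[-1][-1].gene == p.gene:
            groups[-1].append(p)
        else:
            groups.append([p])
    segments = []
    for grp in groups:
        t0 = max(grp[0].t_start, keep_from)
        t1 = grp[-1].t_end
        plen = t1 - t0
        if plen <= 0:
            continue
        # genomic span: clip the first (possibly truncated) piece
        g_spans = []
        for p in grp:
            p0 = max(p.t_start, keep_from)
            off0, off1 = p0 - p.t_start, p.t_end - p.t_start
            if p.strand == "+":
                g_spans.append((p.g_start + off0, p.g_start + off1))
            else:
                g_spans.append((p.g_end - off1, p.g_end - off0))
        g_start = min(s for s, _ in g_spans)
        g_end = max(e for _, e in g_spans)
        # error accounting in post-truncation template coordinates
        k0, k1 = t0 - keep_from, t1 - keep_from
        nsub = int(substituted[k0:k1].sum())
        ndel = int(deleted[k0:k1].sum())
        nins = int(inserted[k0:k1].sum())
        r0, r1 = int(cum[k0]), int(cum[k1])
        if r1 <= r0:
            continue
        segments.append(
            AlignmentSegment(
                read_id=name,
                read_start=r0,
                read_end=r1,
                chrom=grp[0].chrom,
                genome_start=g_start,
                genome_end=g_end,
                align_strand=grp[0].strand,
                matches=max(0, plen - nsub - ndel),
                block_len=plen + nins,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# dataset orchestration


@dataclass
class SimulatedDataset:
    spec: SimSpec
    genome: dict[str, str]
    gene_models: GeneModelSet
    fusions: list[SimulatedFusion]
    reads: list[SimRead]
    truth: list[dict] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return len(self.reads)

    def ideal_segments(self) -> list[AlignmentSegment]:
        return [seg for read in self.reads for seg in read.segments]

    def fusion_read_ids(self) -> set[str]:
        return {r.name for r in self.reads if r.fusion_name is not None}

    def reads_by_id(self) -> dict[str, str]:
        return {r.name: r.seq for r in self.reads}

    # -- writers ------------------------------------------------------------

    def write_genome_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gtf(self, path) -> None:
        write_gene_models(self.gene_models, path)

    def write_reads_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")

    def write_ideal_paf(self, path) -> None:
        read_lengths = {r.name: len(r.seq) for r in self.reads}
        target_lengths = {c: len(s) for c, s in self.genome.items()}
        write_paf(self.ideal_segments(), path, read_lengths, target_lengths)

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tgene5\tgene3\tbreakpoint5\tbreakpoint3\tnum_reads\n")
            for t in self.truth:
                fh.write(
                    f"{t['sample']}\t{t['gene5']}\t{t['gene3']}\t"
                    f"{t['breakpoint5']}\t{t['breakpoint3']}\t{t['num_reads']}\n"
                )

    def write_spec_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self.spec), fh, indent=2, default=list)

    def write_all(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "reads": outdir / "reads.fastq",
            "paf": outdir / "ideal_alignments.paf",
            "truth": outdir / "truth.tsv",
            "spec": outdir / "sim_spec.json",
        }
        self.write_genome_fasta(paths["genome"])
        self.write_gtf(paths["gtf"])
        self.write_reads_fastq(paths["reads"])
        self.write_ideal_paf(paths["paf"])
        self.write_truth_tsv(paths["truth"])
        self.write_spec_json(paths["spec"])
        return paths


def _auto_fusion_plans(spec: SimSpec, gms: GeneModelSet, rng: np.random.Generator):
    """Pair up distinct genes at internal exon junctions."""
    gene_ids = sorted(g.gene_id for g in gms)
    order = list(rng.permutation(len(gene_ids)))
    plans = []
    for i in range(spec.n_fusions):
        g5 = gms[gene_ids[order[2 * i]]]
        g3 = gms[gene_ids[order[2 * i + 1]]]
        n5 = len(next(iter(g5.transcripts.values())))
        n3 = len(next(iter(g3.transcripts.values())))
        donor = int(rng.integers(0, n5 - 1))      # never the last exon
        acceptor = int(rng.integers(1, n3))        # never the first exon
        n_reads = int(rng.integers(spec.fusion_reads[0], spec.fusion_reads[1] + 1))
        plans.append(FusionPlan(g5.gene_id, g3.gene_id, donor, acceptor, n_reads))
    return plans


def _make_read(
    name: str,
    layout: list[TranscriptPiece],
    seq: str,
    fusion_name: str | None,
    spec: SimSpec,
    rng: np.random.Generator,
) -> SimRead:
    keep_from = 0
    if spec.truncation_prob > 0 and rng.random() < spec.truncation_prob:
        frac = rng.uniform(spec.min_retained_frac, 1.0)
        keep_from = int(len(seq) * (1.0 - frac))
    template = seq[keep_from:]
    read_seq, cum, subbed, deled, insed = apply_errors(
        template, rng, spec.sub_rate, spec.ins_rate, spec.del_rate
    )
    segments = _read_segments(name, layout, keep_from, cum, subbed, deled, insed)
    return SimRead(name, read_seq, segments, fusion_name)


def _random_umi(rng: np.random.Generator, k: int = 8) -> str:
    return _random_seq_array(rng, k).tobytes().decode()


def simulate(spec: SimSpec) -> SimulatedDataset:
    """Generate the full dataset described by ``spec`` (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    genome, gms = generate_genome_and_annotation(spec, rng)
    plans = spec.fusions if spec.fusions is not None else _auto_fusion_plans(spec, gms, rng)

    fusions = [construct_fusion_transcript(gms, genome, plan) for plan in plans]
    reads: list[SimRead] = []
    truth: list[dict] = []
    barcode_pool: list[str] = []
    if spec.single_cell:
        barcode_pool = sorted({bc for cells in spec.single_cell.values() for bc in cells})

    for fusion in fusions:
        plan = fusion.plan
        sc_cells = (spec.single_cell or {}).get(plan.name)
        if sc_cells:
            n_total = 0
            for bc in sorted(sc_cells):
                used: set[str] = set()
                for _ in range(sc_cells[bc]):
                    umi = _random_umi(rng)
                    while umi in used:
                        umi = _random_umi(rng)
                    used.add(umi)
                    name = f"{bc}^{umi}^{plan.transcript_id}/{n_total:04d}"
                    reads.append(_make_read(name, fusion.layout, fusion.sequence, plan.name, spec, rng))
                    n_total += 1
        else:
            n_total = plan.n_reads
            for i in range(plan.n_reads):
                name = f"{plan.transcript_id}/{i:04d}"
                reads.append(_make_read(name, fusion.layout, fusion.sequence, plan.name, spec, rng))
        truth.append(
            {
                "sample": "sim",
                "gene5": plan.gene5,
                "gene3": plan.gene3,
                "breakpoint5": fusion.breakpoint5,
                "breakpoint3": fusion.breakpoint3,
                "num_reads": n_total,
            }
        )

    for gene in sorted(gms, key=lambda g: g.gene_id):
        layout = transcript_layout(gene)
        seq = layout_sequence(layout, genome)
        for i in range(spec.background_reads_per_gene):
            name = f"{gene.gene_id}.t1/{i:04d}"
            if barcode_pool:
                bc = barcode_pool[i % len(barcode_pool)]
                name = f"{bc}^{_random_umi(rng)}^{name}"
            reads.append(_make_read(name, layout, seq, None, spec, rng))

    return SimulatedDataset(spec, genome, gms, fusions, reads, truth)
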