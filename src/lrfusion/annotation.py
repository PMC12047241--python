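"""Gene models, the exon-boundary index, and gene-pair similarity lookups.

The annotation layer holds the reference transcript structures that both
phases of fusion calling are computed against: per-gene transcript exon
intervals (internally 0-based, half-open), a per-chromosome index of exon
boundary positions used for breakpoint-to-boundary distances, gene-span
overlap queries, and optional user-supplied exon sequence-similarity and
paralog tables that drive homology-aware filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import gffutils
import numpy as np
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

Interval = tuple[int, int]
Region = tuple[str, int, int]  # chrom, 0-based half-open


class GtfParseError(ValueError):
    """Raised for malformed annotation input, naming the offending line."""


class TableParseError(ValueError):
    """Raised for malformed similarity/paralog/annotation tables."""


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """One gene: transcript structures on a single chromosome and strand."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    transcripts: dict[str, list[Interval]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        for tx_id, exons in self.transcripts.items():
            exons.sort()
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"{self.gene_id}/{tx_id}: overlapping exons [{s1},{e1}) and [{s2},{e2})"
                    )
            for s, e in exons:
                if not 0 <= s < e:
                    raise ValueError(f"{self.gene_id}/{tx_id}: bad exon interval [{s},{e})")

    @property
    def gene_span(self) -> Interval:
        starts = [s for exons in self.transcripts.values() for s, _ in exons]
        ends = [e for exons in self.transcripts.values() for _, e in exons]
        return min(starts), max(ends)

    @cached_property
    def merged_exons(self) -> list[Interval]:
        """Union of exons across all transcripts (collapsed gene model)."""
        all_exons = sorted(
            exon for exons in self.transcripts.values() for exon in exons
        )
        merged: list[list[int]] = []
        for s, e in all_exons:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    @property
    def merged_exon_length(self) -> int:
        return sum(e - s for s, e in self.merged_exons)

    def boundaries(self) -> list[int]:
        """All exon starts and ends over all transcripts (deduplicated)."""
        out = {pos for exons in self.transcripts.values() for s, e in exons for pos in (s, e)}
        return sorted(out)


class GeneModelSet:
    """Collection of :class:`GeneModel` indexed by gene id with exon lookups."""

    def __init__(self, genes) -> None:
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self._exon_trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    @property
    def chroms(self) -> list[str]:
        return sorted({g.chrom for g in self})

    def _trees(self) -> dict[str, IntervalTree]:
        if self._exon_trees is None:
            trees: dict[str, IntervalTree] = {}
            for g in self:
                tree = trees.setdefault(g.chrom, IntervalTree())
                for s, e in g.merged_exons:
                    tree.addi(s, e, g.gene_id)
            self._exon_trees = trees
        return self._exon_trees

    def exonic_overlap(self, chrom: str, start: int, end: int) -> dict[str, int]:
        """Bases of [start, end) overlapping each gene's merged exons."""
        tree = self._trees().get(chrom)
        if tree is None:
            return {}
        out: dict[str, int] = {}
        for iv in tree.overlap(start, end):
            ov = min(end, iv.end) - max(start, iv.begin)
            if ov > 0:
                out[iv.data] = out.get(iv.data, 0) + ov
        return out


# ---------------------------------------------------------------------------
# GTF I/O

_REQUIRED_GTF_FIELDS = 9


def _prevalidate_gtf(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != _REQUIRED_GTF_FIELDS:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GtfParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise GtfParseError(f"{path}: line {lineno}: bad coordinates {start}..{end}")
            if fields[6] not in ("+", "-", "."):
                raise GtfParseError(f"{path}: line {lineno}: bad strand {fields[6]!r}")
            if 'gene_id "' not in fields[8]:
                raise GtfParseError(f"{path}: line {lineno}: missing gene_id attribute")
            if fields[2] == "exon" and 'transcript_id "' not in fields[8]:
                raise GtfParseError(
                    f"{path}: line {lineno}: exon record missing transcript_id attribute"
                )


def parse_gene_models(gtf_path) -> GeneModelSet:
    """Load a GENCODE-style GTF into a :class:`GeneModelSet`.

    GTF 1-based closed coordinates are converted to 0-based half-open.
    An exon whose transcript_id has no transcript record is an error.
    """
    gtf_path = Path(gtf_path)
    _prevalidate_gtf(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    gene_meta: dict[str, tuple[str, str, str]] = {}  # gene_id -> (symbol, chrom, strand)
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        symbol = g.attributes.get("gene_name", [gid])[0]
        gene_meta[gid] = (symbol, g.seqid, g.strand)

    tx_gene: dict[str, str] = {}
    for t in db.features_of_type("transcript"):
        tx_gene[t.attributes["transcript_id"][0]] = t.attributes["gene_id"][0]

    transcripts: dict[str, dict[str, list[Interval]]] = {}
    for ex in db.features_of_type("exon"):
        tx_id = ex.attributes["transcript_id"][0]
        if tx_id not in tx_gene:
            raise GtfParseError(
                f"{gtf_path}: exon at {ex.seqid}:{ex.start}-{ex.end} references "
                f"transcript {tx_id!r} with no transcript record"
            )
        gid = tx_gene[tx_id]
        transcripts.setdefault(gid, {}).setdefault(tx_id, []).append((ex.start - 1, ex.end))

    models = []
    for gid, txs in transcripts.items():
        if gid in gene_meta:
            symbol, chrom, strand = gene_meta[gid]
        else:
            any_tx = next(iter(txs))
            feat = next(db.features_of_type("exon"))  # pragma: no cover - fallback
            symbol, chrom, strand = gid, feat.seqid, feat.strand
        models.append(GeneModel(gid, symbol, chrom, strand, txs))
    return GeneModelSet(models)


def write_gene_models(gms: GeneModelSet, path) -> None:
    """Serialize gene models as GENCODE-dialect GTF (1-based closed)."""
    with open(path, "w") as fh:
        for g in sorted(gms, key=lambda g: (g.chrom, g.gene_span[0], g.gene_id)):
            span_s, span_e = g.gene_span
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tlrfusion\tgene\t{span_s + 1}\t{span_e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tx_id in sorted(g.transcripts):
                exons = g.transcripts[tx_id]
                tx_attrs = f'gene_id "{g.gene_id}"; transcript_id "{tx_id}"; gene_name "{g.symbol}";'
                fh.write(
                    f"{g.chrom}\tlrfusion\ttranscript\t{exons[0][0] + 1}\t{exons[-1][1]}"
                    f"\t.\t{g.strand}\t.\t{tx_attrs}\n"
                )
                for s, e in exons:
                    fh.write(
                        f"{g.chrom}\tlrfusion\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tx_attrs}\n"
                    )


# ---------------------------------------------------------------------------
# exon boundary index


class ExonBoundaryIndex:
    """Sorted per-chromosome exon boundary positions for distance queries.

    Boundaries are the 0-based half-open exon start and end positions of
    every transcript of every gene; an alignment breakpoint that coincides
    with an exon edge therefore has distance 0.
    """

    def __init__(self) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._by_gene: dict[str, np.ndarray] = {}

    @classmethod
    def from_gene_models(cls, gms: GeneModelSet) -> "ExonBoundaryIndex":
        idx = cls()
        per_chrom: dict[str, list[tuple[int, str]]] = {}
        for g in gms:
            bounds = g.boundaries()
            idx._by_gene[g.gene_id] = np.asarray(bounds, dtype=np.int64)
            per_chrom.setdefault(g.chrom, []).extend((b, g.gene_id) for b in bounds)
        for chrom, entries in per_chrom.items():
            entries.sort()
            idx._by_chrom[chrom] = (
                np.asarray([p for p, _ in entries], dtype=np.int64),
                np.asarray([g for _, g in entries], dtype=object),
            )
        return idx

    def min_distance(self, chrom: str, position: int, gene_id: str | None = None):
        """Minimum |position - boundary| and the owning gene.

        Restricting by ``gene_id`` searches only that gene's boundaries.
        Ties are broken toward the smaller genomic coordinate, then the
        lexicographically smaller gene id.
        """
        if gene_id is not None:
            if gene_id not in self._by_gene:
                raise KeyError(f"unknown gene {gene_id!r}")
            arr = self._by_gene[gene_id]
            pos = _nearest(arr, position)
            return int(abs(pos - position)), gene_id
        if chrom not in self._by_chrom:
            raise KeyError(f"no exon boundaries indexed for chromosome {chrom!r}")
        positions, genes = self._by_chrom[chrom]
        best = _nearest(positions, position)
        dist = int(abs(best - position))
        # lexicographically smallest gene among entries at the chosen position
        lo = int(np.searchsorted(positions, best, side="left"))
        hi = int(np.searchsorted(positions, best, side="right"))
        gene = min(genes[lo:hi])
        return dist, str(gene)


def _nearest(arr: np.ndarray, position: int) -> int:
    if arr.size == 0:
        raise KeyError("no boundaries to query")
    i = int(np.searchsorted(arr, position))
    cands = []
    if i > 0:
        cands.append(int(arr[i - 1]))
    if i < arr.size:
        cands.append(int(arr[i]))
    # min distance; ties toward the smaller coordinate
    return min(cands, key=lambda p: (abs(p - position), p))


def min_exon_boundary_distance(chrom: str, position: int, index: ExonBoundaryIndex):
    """Distance from ``position`` to the nearest indexed exon boundary."""
    return index.min_distance(chrom, position)


# ---------------------------------------------------------------------------
# gene span overlap


def overlapping_gene_pairs(gms: GeneModelSet) -> set[frozenset]:
    """Unordered gene pairs whose genomic spans intersect (strand ignored)."""
    pairs: set[frozenset] = set()
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in gms:
        s, e = g.gene_span
        by_chrom.setdefault(g.chrom, []).append((s, e, g.gene_id))
    for spans in by_chrom.values():
        spans.sort()
        active: list[tuple[int, int, str]] = []
        for s, e, gid in spans:
            active = [a for a in active if a[1] > s]
            for _, ae, agid in active:
                pairs.add(frozenset((gid, agid)))
            active.append((s, e, gid))
    return pairs


# ---------------------------------------------------------------------------
# similarity map


def parse_region(text: str) -> Region:
    """Parse ``chrom:start-end`` (1-based closed) into 0-based half-open."""
    try:
        chrom, span = text.rsplit(":", 1)
        s, e = span.split("-")
        start, end = int(s) - 1, int(e)
    except ValueError:
        raise TableParseError(f"bad region {text!r}; expected chrom:start-end") from None
    if start < 0 or end <= start:
        raise TableParseError(f"bad region {text!r}; empty or negative interval")
    return chrom, start, end


@dataclass
class SimilarityMap:
    """Symmetric lookup of sequence-similar exon regions and paralog pairs."""

    _regions: dict[tuple[str, str], list[tuple[Region, Region]]] = field(default_factory=dict)
    paralogs: set[frozenset] = field(default_factory=set)

    def add(self, gene_a: str, gene_b: str, region_a: Region, region_b: Region) -> None:
        if gene_a <= gene_b:
            key, pair = (gene_a, gene_b), (region_a, region_b)
        else:
            key, pair = (gene_b, gene_a), (region_b, region_a)
        self._regions.setdefault(key, []).append(pair)

    def lookup(self, gene_a: str, gene_b: str) -> list[tuple[Region, Region]]:
        """Similar region pairs, first element belonging to ``gene_a``."""
        key = (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)
        pairs = self._regions.get(key, [])
        if gene_a <= gene_b:
            return list(pairs)
        return [(rb, ra) for ra, rb in pairs]

    def similar_regions_of(self, gene: str, partner: str) -> list[Region]:
        """Regions of ``gene`` flagged as similar to ``partner``."""
        return [ra for ra, _ in self.lookup(gene, partner)]

    def is_paralog_pair(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.paralogs

    def __bool__(self) -> bool:
        return bool(self._regions) or bool(self.paralogs)


def load_similarity_and_paralogs(similarity_tsv=None, paralog_tsv=None) -> SimilarityMap:
    """Load optional similarity / paralog tables; absent files disable filters."""
    smap = SimilarityMap()
    if similarity_tsv is not None and Path(similarity_tsv).exists():
        with open(similarity_tsv) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 4:
                    raise TableParseError(
                        f"{similarity_tsv}: line {lineno}: expected 4 columns "
                        f"(geneA, geneB, regionA, regionB), got {len(fields)}"
                    )
                try:
                    ra, rb = parse_region(fields[2]), parse_region(fields[3])
                except TableParseError as exc:
                    raise TableParseError(f"{similarity_tsv}: line {lineno}: {exc}") from None
                smap.add(fields[0], fields[1], ra, rb)
    elif similarity_tsv is not None:
        log.warning("similarity table %s not found; similarity filtering disabled", similarity_tsv)
    else:
        log.info("no similarity table supplied; similarity filtering disabled")

    if paralog_tsv is not None and Path(paralog_tsv).exists():
        with open(paralog_tsv) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise TableParseError(
                        f"{paralog_tsv}: line {lineno}: expected 2 columns, got {len(fields)}"
                    )
                smap.paralogs.add(frozenset(fields[:2]))
    elif paralog_tsv is not None:
        log.warning("paralog table %s not found; paralog filtering disabled", paralog_tsv)
    return smap
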