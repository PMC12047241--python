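"""Per-cell fusion evidence via barcode/UMI read-name tagging.

Single-cell reads carry their cell barcode and UMI encoded in the read name
(``<barcode>^<umi>^<core_id>`` by default); the fusion report's supporting
read names are decoded back into per-cell, UMI-deduplicated fusion counts,
and somatic fusions are selected by tumor-cell support filters (minimum
tumor cells, minimum tumor fraction, absence from a matched normal).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

log = logging.getLogger(__name__)

DEFAULT_DELIMITER = "^"
_BARCODE_RE = re.compile(r"^[ACGTN]+$")


class ReadNameError(ValueError):
    pass


@dataclass(frozen=True)
class TaggedRead:
    barcode: str
    umi: str
    core_read_id: str


def encode_read_name(
    barcode: str, umi: str, core_read_id: str, delimiter: str = DEFAULT_DELIMITER
) -> str:
    """Encode barcode and UMI into a read name; fields must be delimiter-free."""
    for label, value in (("barcode", barcode), ("umi", umi), ("core_read_id", core_read_id)):
        if not value:
            raise ReadNameError(f"{label} must be non-empty")
    for label, value in (("barcode", barcode), ("umi", umi)):
        if delimiter in value:
            raise ReadNameError(f"{label} {value!r} contains the delimiter {delimiter!r}")
    if not _BARCODE_RE.match(barcode):
        log.debug("barcode %r is not plain ACGTN; passing through verbatim", barcode)
    return f"{barcode}{delimiter}{umi}{delimiter}{core_read_id}"


def parse_tagged_read_name(read_name: str, delimiter: str = DEFAULT_DELIMITER) -> TaggedRead:
    """Decode ``<barcode>^<umi>^<core_id>``; inverse of :func:`encode_read_name`."""
    parts = read_name.split(delimiter, 2)
    if len(parts) != 3 or not all(parts):
        raise ReadNameError(
            f"read name {read_name!r} is not barcode{delimiter}umi{delimiter}core_id"
        )
    return TaggedRead(*parts)


# ---------------------------------------------------------------------------
# cell x fusion matrix


@dataclass
class CellFusionMatrix:
    """Sparse (barcode, fusion) -> deduplicated count with per-cell totals."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def barcodes(self) -> list[str]:
        return sorted({bc for bc, _ in self.counts})

    @property
    def fusions(self) -> list[str]:
        return sorted({f for _, f in self.counts})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def cell_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (bc, _), n in self.counts.items():
            out[bc] = out.get(bc, 0) + n
        return out

    def fusion_cells(self, fusion: str) -> set[str]:
        return {bc for (bc, f), n in self.counts.items() if f == fusion and n > 0}

    def has_fusion(self, fusion: str) -> bool:
        return any(f == fusion and n > 0 for (_, f), n in self.counts.items())

    def restrict_to_cell(self, barcode: str) -> "CellFusionMatrix":
        return CellFusionMatrix({k: n for k, n in self.counts.items() if k[0] == barcode})

    def to_long_frame(self) -> pd.DataFrame:
        records = [
            {"barcode": bc, "fusion": f, "count": n}
            for (bc, f), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(records, columns=["barcode", "fusion", "count"])

    def write_long_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    def write_mtx(self, outdir) -> None:
        """MatrixMarket triplet plus row (barcode) / column (fusion) names."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        barcodes, fusions = self.barcodes, self.fusions
        bc_idx = {b: i for i, b in enumerate(barcodes)}
        f_idx = {f: i for i, f in enumerate(fusions)}
        mat = scipy.sparse.coo_matrix(
            (
                [n for n in self.counts.values()],
                (
                    [bc_idx[bc] for bc, _ in self.counts],
                    [f_idx[f] for _, f in self.counts],
                ),
            ),
            shape=(max(len(barcodes), 1), max(len(fusions), 1)),
        )
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat)
        (outdir / "barcodes.tsv").write_text("".join(b + "\n" for b in barcodes))
        (outdir / "fusions.tsv").write_text("".join(f + "\n" for f in fusions))


def _iter_fusion_reads(report):
    """Yield (fusion_name, read_id) from report rows or a report DataFrame."""
    if isinstance(report, pd.DataFrame):
        for _, row in report.iterrows():
            ids = row["LongReadIds"]
            if isinstance(ids, str) and ids:
                for rid in ids.split(","):
                    yield row["#FusionName"], rid
    else:
        for row in report:
            for rid in row.read_ids:
                yield row.fusion_name, rid


def build_cell_fusion_matrix(
    report,
    delimiter: str = DEFAULT_DELIMITER,
    count_umis: bool = True,
    allow_untagged: bool = False,
) -> CellFusionMatrix:
    """Per-cell fusion counts from the report's supporting read names.

    Counts distinct UMIs per (cell, fusion) by default (duplicate UMIs
    collapse to one); ``count_umis=False`` counts reads instead. Untagged
    read names raise unless ``allow_untagged``.
    """
    umis: dict[tuple[str, str], set[str]] = {}
    read_counts: dict[tuple[str, str], int] = {}
    for fusion, rid in _iter_fusion_reads(report):
        try:
            tag = parse_tagged_read_name(rid, delimiter)
        except ReadNameError:
            if allow_untagged:
                log.warning("untagged read %r skipped", rid)
                continue
            raise
        key = (tag.barcode, fusion)
        umis.setdefault(key, set()).add(tag.umi)
        read_counts[key] = read_counts.get(key, 0) + 1
    source = {k: len(v) for k, v in umis.items()} if count_umis else read_counts
    return CellFusionMatrix(dict(sorted(source.items())))


# ---------------------------------------------------------------------------
# somatic cell filters


def read_cell_annotations(path) -> dict[str, str]:
    """Cell annotation TSV: barcode <tab> cell_type."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.lower().startswith("barcode\t"):
                continue
            bc, cell_type = line.rstrip("\n").split("\t")[:2]
            out[bc] = cell_type
    return out


def filter_somatic_cell_fusions(
    matrix: CellFusionMatrix,
    cell_annotations: dict[str, str],
    matched_normal: CellFusionMatrix | None = None,
    min_cells: int = 5,
    min_tumor_fraction: float = 0.8,
    tumor_label: str = "tumor",
) -> list[str]:
    """Fusions supported by enough tumor cells and absent from the normal.

    A fusion is kept when at least ``min_cells`` tumor cells show evidence,
    at least ``min_tumor_fraction`` of its annotated fusion-positive cells
    are tumor, and it is absent from the matched normal matrix (when one is
    supplied). Barcodes missing from the annotations are warned about and
    excluded from the fraction denominator.
    """
    kept = []
    for fusion in matrix.fusions:
        cells = matrix.fusion_cells(fusion)
        annotated = []
        for bc in cells:
            if bc not in cell_annotations:
                log.warning("barcode %s missing from cell annotations; excluded", bc)
                continue
            annotated.append(bc)
        tumor_cells = [bc for bc in annotated if cell_annotations[bc] == tumor_label]
        if len(tumor_cells) < min_cells:
            continue
        if not annotated or len(tumor_cells) / len(annotated) < min_tumor_fraction:
            continue
        if matched_normal is not None and matched_normal.has_fusion(fusion):
            continue
        kept.append(fusion)
    return kept
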