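"""Fusion-prediction benchmarking: matching, scoring, PR curves, truth sets.

Implements gene-pair matching with identity/paralog/genomic-overlap proxies
in strict (ordered) and allow-reverse (unordered) modes, exact and fuzzy
(+/- 5 base) breakpoint comparison on order-sorted breakpoint pairs,
TP/FP/FN scoring with optional unique-prediction FPs, precision/recall/F1
and the trapezoidal precision-recall AUC over read-support thresholds,
"wisdom of the crowds" proxy truth sets (fusions agreed by a minimum number
of methods after read filtering), and nuisance-fusion filtering
(mitochondrial/HLA/immunoglobulin partners, neighbors within 100 kb,
known-normal fusions, promiscuous genes across samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModelSet, SimilarityMap

log = logging.getLogger(__name__)

Breakpoint = tuple[str, int]  # chrom, 1-based position


def parse_breakpoint(text) -> Breakpoint | None:
    """Parse ``chrom:pos`` or ``chrom:pos:strand`` (strand ignored)."""
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return None
    parts = str(text).split(":")
    if len(parts) < 2:
        raise ValueError(f"bad breakpoint {text!r}; expected chrom:pos[:strand]")
    return parts[0], int(parts[1])


@dataclass(frozen=True)
class PredictedFusion:
    """One method's fusion call on one sample."""

    method: str
    sample: str
    gene5: str
    gene3: str
    breakpoint5: Breakpoint | None = None
    breakpoint3: Breakpoint | None = None
    read_support: int = 1

    def __post_init__(self) -> None:
        if self.read_support < 1:
            raise ValueError("read_support must be >= 1")

    @property
    def pair(self) -> tuple[str, str]:
        return self.gene5, self.gene3

    @property
    def name(self) -> str:
        return f"{self.gene5}--{self.gene3}"


@dataclass
class MatchConfig:
    """How predictions are compared with truth entries."""

    mode: str = "strict"  # 'strict' | 'allow_reverse'
    breakpoints: str = "ignore"  # 'exact' | 'fuzzy' | 'ignore'
    fuzzy_window: int = 5
    similarity: SimilarityMap | None = None
    overlapping_pairs: set | frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "allow_reverse"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.breakpoints not in ("exact", "fuzzy", "ignore"):
            raise ValueError(f"unknown breakpoint mode {self.breakpoints!r}")


def genes_equivalent(a: str, b: str, config: MatchConfig) -> bool:
    """Identity, paralogy, or genomic-overlap proxy equivalence."""
    if a == b:
        return True
    if config.similarity is not None and config.similarity.is_paralog_pair(a, b):
        return True
    return frozenset((a, b)) in config.overlapping_pairs


def gene_pair_match(pred, truth_set, config: MatchConfig):
    """First truth entry whose gene pair matches the prediction, else None.

    Strict mode compares the ordered (gene5, gene3) pair side by side;
    allow-reverse additionally tries the swapped prediction order. Each
    side may match via identity, paralogy, or genomic overlap.
    """
    orders = [(pred.gene5, pred.gene3)]
    if config.mode == "allow_reverse":
        orders.append((pred.gene3, pred.gene5))
    for truth in truth_set:
        for g5, g3 in orders:
            if genes_equivalent(g5, truth.gene5, config) and genes_equivalent(
                g3, truth.gene3, config
            ):
                return truth
    return None


def breakpoint_match(pred_bkpts, truth_bkpts, mode: str = "exact", window: int = 5) -> bool:
    """Compare two breakpoint pairs, ignoring breakpoint ordering.

    Pairs are first sorted canonically by (chrom, position). Exact mode
    requires both coordinates identical; fuzzy mode allows each to lie
    within ``window`` bases of its counterpart.
    """
    p = sorted(b for b in pred_bkpts if b is not None)
    t = sorted(b for b in truth_bkpts if b is not None)
    if len(p) != 2 or len(t) != 2:
        return False
    for (pc, pp), (tc, tp) in zip(p, t):
        if pc != tc:
            return False
        if mode == "exact":
            if pp != tp:
                return False
        elif abs(pp - tp) > window:
            return False
    return True


def _pred_matches_truth(pred, truth, config: MatchConfig) -> bool:
    if gene_pair_match(pred, [truth], config) is None:
        return False
    if config.breakpoints == "ignore":
        return True
    return breakpoint_match(
        (pred.breakpoint5, pred.breakpoint3),
        (truth.breakpoint5, truth.breakpoint3),
        mode=config.breakpoints,
        window=config.fuzzy_window,
    )


# ---------------------------------------------------------------------------
# scoring


@dataclass
class ScoreResult:
    tp: list
    fp: list
    fn: list

    @property
    def precision(self) -> float:
        denom = len(self.tp) + len(self.fp)
        return len(self.tp) / denom if denom else 1.0

    @property
    def recall(self) -> float:
        denom = len(self.tp) + len(self.fn)
        return len(self.tp) / denom if denom else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def score_predictions(
    predictions,
    truth,
    min_reads: int = 1,
    config: MatchConfig | None = None,
    cross_method_predictions=None,
) -> ScoreResult:
    """TP/FP/FN sets for one method's predictions against a truth set.

    A truth entry matched by any prediction counts once as TP; unmatched
    truth entries are FN; unmatched predictions are FP. When a cross-method
    prediction table is supplied, only fusions uniquely predicted by this
    method are scored as FPs (shared unmatched predictions are ignored).
    """
    config = config or MatchConfig()
    preds = [p for p in predictions if p.read_support >= min_reads]
    matched_truth = []
    unmatched_preds = []
    truth = list(truth)
    for p in preds:
        hit = next((t for t in truth if _pred_matches_truth(p, t, config)), None)
        if hit is not None:
            if hit not in matched_truth:
                matched_truth.append(hit)
        else:
            unmatched_preds.append(p)
    fn = [t for t in truth if t not in matched_truth]
    fp = unmatched_preds
    if cross_method_predictions is not None:
        unordered = MatchConfig(
            mode="allow_reverse",
            similarity=config.similarity,
            overlapping_pairs=config.overlapping_pairs,
        )
        fp = [
            p
            for p in unmatched_preds
            if not any(
                o.method != p.method and gene_pair_match(p, [o], unordered) is not None
                for o in cross_method_predictions
            )
        ]
    return ScoreResult(tp=matched_truth, fp=fp, fn=fn)


@dataclass(frozen=True)
class PRPoint:
    threshold: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    no_predictions: bool = False


def pr_curve(
    predictions, truth, thresholds=None, config: MatchConfig | None = None,
    cross_method_predictions=None,
) -> list[PRPoint]:
    """One precision/recall point per minimum-read-support threshold."""
    predictions = list(predictions)
    if thresholds is None:
        max_support = max((p.read_support for p in predictions), default=1)
        thresholds = range(1, max_support + 1)
    points = []
    for t in thresholds:
        score = score_predictions(predictions, truth, t, config, cross_method_predictions)
        no_preds = not score.tp and not score.fp
        points.append(
            PRPoint(
                threshold=int(t),
                tp=len(score.tp),
                fp=len(score.fp),
                fn=len(score.fn),
                precision=score.precision,
                recall=score.recall,
                f1=score.f1,
                no_predictions=no_preds,
            )
        )
    return points


def pr_auc(points) -> float:
    """Trapezoidal area under precision over recall.

    Points flagged as having no retained predictions are excluded. The
    curve is extended horizontally to recall 0 from the highest-precision
    point. Degenerate input (no usable points) yields 0.
    """
    usable = [(p.recall, p.precision) for p in points if not p.no_predictions]
    if not usable:
        return 0.0
    pts = sorted(set(usable))
    best_precision = max(p for _, p in pts)
    if pts[0][0] > 0:
        pts.insert(0, (0.0, best_precision))
    recalls = np.array([r for r, _ in pts])
    precisions = np.array([p for _, p in pts])
    return float(np.trapezoid(precisions, recalls))


def pr_curve_auc(predictions, truth, thresholds=None, config=None, cross_method_predictions=None):
    points = pr_curve(predictions, truth, thresholds, config, cross_method_predictions)
    return points, pr_auc(points)


# ---------------------------------------------------------------------------
# proxy truth sets


@dataclass
class ProxyTruthSet:
    """Operational truth: fusions agreed upon by enough methods."""

    min_reads: int
    min_methods: int
    entries: list[PredictedFusion]

    @property
    def pairs(self) -> set[frozenset]:
        return {frozenset(e.pair) for e in self.entries}


def build_proxy_truth(
    predictions_by_method: dict[str, list],
    min_reads: int = 3,
    min_methods: int = 2,
    config: MatchConfig | None = None,
) -> ProxyTruthSet:
    """Wisdom-of-the-crowds truth: per-method read filtering, then fusions
    predicted by at least ``min_methods`` distinct methods (unordered pairs,
    with paralog/overlap proxies when a :class:`MatchConfig` provides them).
    """
    config = config or MatchConfig()
    unordered = MatchConfig(
        mode="allow_reverse",
        similarity=config.similarity,
        overlapping_pairs=config.overlapping_pairs,
    )
    filtered = {
        m: [p for p in preds if p.read_support >= min_reads]
        for m, preds in predictions_by_method.items()
    }
    entries = []
    seen_pairs: list[PredictedFusion] = []
    for method, preds in sorted(filtered.items()):
        for p in preds:
            if any(gene_pair_match(p, [e], unordered) for e in seen_pairs):
                continue
            supporters = {
                m
                for m, others in filtered.items()
                if any(gene_pair_match(p, [o], unordered) for o in others)
            }
            if len(supporters) >= min_methods:
                entries.append(p)
                seen_pairs.append(p)
    return ProxyTruthSet(min_reads=min_reads, min_methods=min_methods, entries=entries)


def proxy_truth_grid(
    predictions_by_method,
    read_thresholds=range(1, 11),
    method_counts=(2, 3, 4),
    config=None,
):
    """The 3 x 10 sweep of proxy truth sets over read/method thresholds."""
    return {
        (r, m): build_proxy_truth(predictions_by_method, r, m, config)
        for m in method_counts
        for r in read_thresholds
    }


# ---------------------------------------------------------------------------
# nuisance filtering


@dataclass
class NuisanceLists:
    mito_genes: set[str] = field(default_factory=set)
    hla_genes: set[str] = field(default_factory=set)
    ig_genes: set[str] = field(default_factory=set)
    normal_pairs: set[frozenset] = field(default_factory=set)

    @property
    def flagged_genes(self) -> set[str]:
        return self.mito_genes | self.hla_genes | self.ig_genes


def _span_gap(gms: GeneModelSet, a: str, b: str) -> int | None:
    if a not in gms or b not in gms:
        return None
    ga, gb = gms[a], gms[b]
    if ga.chrom != gb.chrom:
        return None
    (s1, e1), (s2, e2) = ga.gene_span, gb.gene_span
    return max(s1, s2) - min(e1, e2)


def promiscuous_genes(
    cross_sample_predictions, min_methods: int = 2, min_samples: int = 2
) -> set[str]:
    """Genes appearing in fusion calls of multiple methods across samples."""
    methods: dict[str, set[str]] = {}
    samples: dict[str, set[str]] = {}
    for p in cross_sample_predictions:
        for gene in p.pair:
            methods.setdefault(gene, set()).add(p.method)
            samples.setdefault(gene, set()).add(p.sample)
    return {
        g
        for g in methods
        if len(methods[g]) >= min_methods and len(samples[g]) >= min_samples
    }


def nuisance_filter(
    predictions,
    gms: GeneModelSet | None = None,
    lists: NuisanceLists | None = None,
    cross_sample_predictions=None,
    neighbor_distance: int = 100_000,
    min_methods: int = 2,
    min_samples: int = 2,
):
    """Remove likely-artifactual fusions before benchmarking.

    Drops fusions with a mitochondrial/HLA/immunoglobulin partner, fusions
    on the known-normal pair list, same-chromosome pairs whose gene spans
    lie within ``neighbor_distance`` (gap <= distance, overlap included),
    and, when a cross-sample table is given, fusions containing promiscuous
    genes.
    """
    lists = lists or NuisanceLists()
    promiscuous = (
        promiscuous_genes(cross_sample_predictions, min_methods, min_samples)
        if cross_sample_predictions is not None
        else set()
    )
    retained = []
    for p in predictions:
        if set(p.pair) & lists.flagged_genes:
            continue
        if frozenset(p.pair) in lists.normal_pairs:
            continue
        if set(p.pair) & promiscuous:
            continue
        if gms is not None:
            gap = _span_gap(gms, p.gene5, p.gene3)
            if gap is not None and gap <= neighbor_distance:
                continue
        retained.append(p)
    return retained


# ---------------------------------------------------------------------------
# TSV interfaces


def read_predictions_tsv(path, method: str | None = None) -> list[PredictedFusion]:
    """Per-method prediction TSV: sample, gene5, gene3, breakpoint5,
    breakpoint3, num_reads (breakpoints may be empty)."""
    df = pd.read_csv(path, sep="\t")
    method = method or Path(path).stem
    out = []
    for _, row in df.iterrows():
        out.append(
            PredictedFusion(
                method=method,
                sample=str(row.get("sample", "sample")),
                gene5=str(row["gene5"]),
                gene3=str(row["gene3"]),
                breakpoint5=parse_breakpoint(row.get("breakpoint5")),
                breakpoint3=parse_breakpoint(row.get("breakpoint3")),
                read_support=int(row["num_reads"]),
            )
        )
    return out


def read_truth_tsv(path) -> list[PredictedFusion]:
    return read_predictions_tsv(path, method="truth")


def predictions_from_report(report_df: pd.DataFrame, method: str, sample: str):
    """Adapt a fusion report DataFrame into benchmark predictions."""
    out = []
    for _, row in report_df.iterrows():
        out.append(
            PredictedFusion(
                method=method,
                sample=sample,
                gene5=str(row["LeftGene"]),
                gene3=str(row["RightGene"]),
                breakpoint5=parse_breakpoint(row["LeftBreakpoint"]),
                breakpoint3=parse_breakpoint(row["RightBreakpoint"]),
                read_support=int(row["NumLongReads"]),
            )
        )
    return out


def write_pr_table(points, path) -> None:
    pd.DataFrame([vars(p) for p in points]).to_csv(path, sep="\t", index=False)
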