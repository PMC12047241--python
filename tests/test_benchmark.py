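"""Benchmarking: matching modes, scoring, PR curves, truth sets, nuisance."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.integrate

from lrfusion.annotation import SimilarityMap
from lrfusion.benchmark import (
    MatchConfig,
    NuisanceLists,
    PredictedFusion,
    breakpoint_match,
    build_proxy_truth,
    gene_pair_match,
    nuisance_filter,
    parse_breakpoint,
    pr_auc,
    pr_curve,
    pr_curve_auc,
    promiscuous_genes,
    score_predictions,
)


def pf(g5, g3, method="m1", sample="s1", reads=1, bp5=None, bp3=None):
    return PredictedFusion(method, sample, g5, g3, bp5, bp3, reads)


# ---------------------------------------------------------------------------
# gene pair matching


def test_strict_and_allow_reverse_modes():
    truth = [pf("A", "B", method="truth")]
    assert gene_pair_match(pf("A", "B"), truth, MatchConfig("strict")) is not None
    assert gene_pair_match(pf("B", "A"), truth, MatchConfig("strict")) is None
    assert gene_pair_match(pf("B", "A"), truth, MatchConfig("allow_reverse")) is not None


def test_paralog_and_overlap_proxies():
    truth = [pf("A", "B", method="truth")]
    smap = SimilarityMap(paralogs={frozenset(("A", "Aprime"))})
    cfg = MatchConfig("strict", similarity=smap)
    assert gene_pair_match(pf("Aprime", "B"), truth, cfg) is not None
    cfg2 = MatchConfig("strict", overlapping_pairs={frozenset(("B", "Bov"))})
    assert gene_pair_match(pf("A", "Bov"), truth, cfg2) is not None
    assert gene_pair_match(pf("Aprime", "B"), truth, MatchConfig("strict")) is None


# ---------------------------------------------------------------------------
# breakpoint matching


def test_breakpoint_exact_and_fuzzy():
    t = (("chr1", 100), ("chr2", 500))
    assert breakpoint_match(t, t, "exact")
    shifted = (("chr1", 105), ("chr2", 495))
    assert not breakpoint_match(shifted, t, "exact")
    assert breakpoint_match(shifted, t, "fuzzy")
    assert not breakpoint_match((("chr1", 106), ("chr2", 500)), t, "fuzzy")


def test_breakpoint_order_ignored():
    t = (("chr1", 100), ("chr2", 500))
    swapped = (("chr2", 500), ("chr1", 100))
    assert breakpoint_match(swapped, t, "exact")
    assert breakpoint_match(swapped, t, "fuzzy")


def test_breakpoint_chromosome_must_match():
    assert not breakpoint_match((("chr1", 100), ("chr2", 500)),
                                (("chr3", 100), ("chr2", 500)), "fuzzy")


def test_parse_breakpoint_formats():
    assert parse_breakpoint("chr1:100") == ("chr1", 100)
    assert parse_breakpoint("chr1:100:+") == ("chr1", 100)
    assert parse_breakpoint(None) is None
    with pytest.raises(ValueError):
        parse_breakpoint("chr1")


# ---------------------------------------------------------------------------
# scoring


def test_perfect_predictions():
    truth = [pf("A", "B", method="truth"), pf("C", "D", method="truth")]
    preds = [pf("A", "B"), pf("C", "D")]
    s = score_predictions(preds, truth)
    assert (len(s.tp), len(s.fp), len(s.fn)) == (2, 0, 0)
    assert s.precision == s.recall == s.f1 == 1.0


def test_set_arithmetic():
    truth = [pf("X1", "X2", method="truth"), pf("Y1", "Y2", method="truth")]
    preds = [pf("X1", "X2"), pf("Z1", "Z2")]
    s = score_predictions(preds, truth)
    assert [t.name for t in s.tp] == ["X1--X2"]
    assert [t.name for t in s.fn] == ["Y1--Y2"]
    assert [p.name for p in s.fp] == ["Z1--Z2"]


def test_unique_fp_scoring():
    """Shared (cross-method) non-truth predictions are not scored as FPs."""
    truth = [pf("X1", "X2", method="truth")]
    preds = [pf("X1", "X2"), pf("Z1", "Z2")]
    cross = preds + [pf("Z2", "Z1", method="m2")]  # other method agrees on Z
    s = score_predictions(preds, truth, cross_method_predictions=cross)
    assert s.fp == []
    cross_disjoint = preds + [pf("W1", "W2", method="m2")]
    s2 = score_predictions(preds, truth, cross_method_predictions=cross_disjoint)
    assert [p.name for p in s2.fp] == ["Z1--Z2"]


def test_truth_entry_counted_once():
    truth = [pf("A", "B", method="truth")]
    preds = [pf("A", "B", bp5=("c", 1)), pf("A", "B", bp5=("c", 2))]
    s = score_predictions(preds, truth)
    assert len(s.tp) == 1 and s.precision == 1.0


def test_min_reads_monotonicity():
    truth = [pf("A", "B", method="truth"), pf("C", "D", method="truth")]
    preds = [pf("A", "B", reads=5), pf("C", "D", reads=2), pf("E", "F", reads=9)]
    tps = [len(score_predictions(preds, truth, t).tp) for t in range(1, 11)]
    assert all(a >= b for a, b in zip(tps, tps[1:]))


# ---------------------------------------------------------------------------
# PR curves and AUC


def test_perfect_predictor_auc():
    truth = [pf("A", "B", method="truth"), pf("C", "D", method="truth")]
    preds = [pf("A", "B", reads=5), pf("C", "D", reads=5)]
    points, auc = pr_curve_auc(preds, truth, thresholds=range(1, 6))
    assert auc == pytest.approx(1.0)
    assert all(p.precision == 1.0 and p.recall == 1.0 for p in points)


def test_single_point_extension():
    """P=1 at R=0.5, extended horizontally to recall 0 -> area 0.5."""
    truth = [pf("A", "B", method="truth"), pf("C", "D", method="truth")]
    preds = [pf("A", "B", reads=1)]
    points, auc = pr_curve_auc(preds, truth, thresholds=[1])
    assert points[0].precision == 1.0 and points[0].recall == 0.5
    assert auc == pytest.approx(0.5)


def test_degenerate_no_predictions():
    truth = [pf("A", "B", method="truth")]
    points, auc = pr_curve_auc([pf("X", "Y", reads=1)], truth, thresholds=[5])
    assert points[0].no_predictions
    assert auc == 0.0


def test_auc_matches_numerical_integration_oracle():
    """Trapezoid AUC equals piecewise-linear quadrature to 1e-12."""
    rng = np.random.default_rng(99)
    for _ in range(20):
        n_truth, n_extra = int(rng.integers(2, 8)), int(rng.integers(0, 6))
        truth = [pf(f"T{i}a", f"T{i}b", method="truth") for i in range(n_truth)]
        preds = [
            pf(f"T{i}a", f"T{i}b", reads=int(rng.integers(1, 10)))
            for i in range(n_truth)
            if rng.random() < 0.8
        ] + [pf(f"F{j}a", f"F{j}b", reads=int(rng.integers(1, 10))) for j in range(n_extra)]
        if not preds:
            continue
        points, auc = pr_curve_auc(preds, truth)
        usable = sorted({(p.recall, p.precision) for p in points if not p.no_predictions})
        if not usable:
            assert auc == 0.0
            continue
        best = max(p for _, p in usable)
        if usable[0][0] > 0:
            usable.insert(0, (0.0, best))
        xs = [r for r, _ in usable]
        ys = [p for _, p in usable]
        expected = 0.0
        for (x0, y0), (x1, y1) in zip(usable, usable[1:]):
            val, _ = scipy.integrate.quad(lambda x: np.interp(x, xs, ys), x0, x1)
            expected += val
        assert abs(auc - expected) <= 1e-12


# ---------------------------------------------------------------------------
# proxy truth sets


def _toy_method_calls():
    return {
        "m1": [pf("A", "B", "m1", reads=5), pf("C", "D", "m1", reads=2), pf("E", "F", "m1", reads=9)],
        "m2": [pf("B", "A", "m2", reads=4), pf("C", "D", "m2", reads=7)],
        "m3": [pf("C", "D", "m3", reads=3), pf("G", "H", "m3", reads=6)],
        "m4": [pf("E", "F", "m4", reads=2)],
    }


def test_proxy_truth_examples():
    calls = _toy_method_calls()
    truth = build_proxy_truth(calls, min_reads=3, min_methods=2)
    assert truth.pairs == {frozenset(("A", "B")), frozenset(("C", "D"))}
    # a pair called by a single method is never truth
    truth1 = build_proxy_truth(calls, min_reads=1, min_methods=2)
    assert frozenset(("G", "H")) not in truth1.pairs


def test_proxy_truth_matches_exhaustive_enumeration():
    calls = _toy_method_calls()
    for min_reads in range(1, 11):
        for min_methods in (2, 3, 4):
            got = build_proxy_truth(calls, min_reads, min_methods).pairs
            support: dict[frozenset, set[str]] = {}
            for m, preds in calls.items():
                for p in preds:
                    if p.read_support >= min_reads:
                        support.setdefault(frozenset(p.pair), set()).add(m)
            expected = {pair for pair, ms in support.items() if len(ms) >= min_methods}
            assert got == expected, (min_reads, min_methods)


# ---------------------------------------------------------------------------
# nuisance filtering


def test_flagged_gene_partners_removed():
    lists = NuisanceLists(mito_genes={"MT-CO1"}, hla_genes={"HLA-A"}, ig_genes={"IGHV1"})
    preds = [pf("MT-CO1", "X"), pf("Y", "HLA-A"), pf("IGHV1", "Z"), pf("P", "Q")]
    out = nuisance_filter(preds, lists=lists)
    assert [p.name for p in out] == ["P--Q"]


def test_known_normal_pairs_removed():
    lists = NuisanceLists(normal_pairs={frozenset(("A", "B"))})
    assert nuisance_filter([pf("B", "A"), pf("C", "D")], lists=lists)[0].name == "C--D"


def test_neighbor_distance_rule():
    """Same-chromosome pairs within 100 kb (span gap) are removed."""
    from lrfusion.annotation import GeneModel, GeneModelSet

    gms = GeneModelSet(
        [
            GeneModel("N1", "N1", "c", "+", {"t": [(0, 10_000)]}),
            GeneModel("N2", "N2", "c", "+", {"t": [(90_000, 95_000)]}),   # gap 80 kb
            GeneModel("N3", "N3", "c", "+", {"t": [(130_000, 140_000)]}),  # gap 120 kb from N1
        ]
    )
    preds = [pf("N1", "N2"), pf("N1", "N3")]
    out = nuisance_filter(preds, gms=gms)
    assert [p.name for p in out] == ["N1--N3"]


def test_promiscuous_genes_detected_and_removed():
    cross = [
        pf("PROM", "X1", "m1", "s1"),
        pf("PROM", "X2", "m2", "s2"),
        pf("PROM", "X3", "m1", "s3"),
        pf("QUIET", "X4", "m1", "s1"),
    ]
    assert promiscuous_genes(cross) == {"PROM"}
    out = nuisance_filter([pf("PROM", "Y"), pf("QUIET", "Y")], cross_sample_predictions=cross)
    assert [p.name for p in out] == ["QUIET--Y"]


# ---------------------------------------------------------------------------
# containment properties


def _random_instance(rng):
    genes = [f"G{i}" for i in range(6)]
    g5, g3 = rng.choice(genes, size=2, replace=False)
    t5, t3 = rng.choice(genes, size=2, replace=False)
    bp = lambda: (f"chr{rng.integers(1, 3)}", int(rng.integers(1, 30)))
    return (
        pf(g5, g3, bp5=bp(), bp3=bp()),
        pf(t5, t3, method="truth", bp5=bp(), bp3=bp()),
    )


def test_strict_subset_of_allow_reverse_and_exact_subset_of_fuzzy():
    rng = np.random.default_rng(1234)
    strict, reverse = MatchConfig("strict"), MatchConfig("allow_reverse")
    for _ in range(10_000):
        pred, truth = _random_instance(rng)
        if gene_pair_match(pred, [truth], strict):
            assert gene_pair_match(pred, [truth], reverse)
        p_bp = (pred.breakpoint5, pred.breakpoint3)
        t_bp = (truth.breakpoint5, truth.breakpoint3)
        if breakpoint_match(p_bp, t_bp, "exact"):
            assert breakpoint_match(p_bp, t_bp, "fuzzy")


def test_metric_bounds():
    rng = np.random.default_rng(77)
    for _ in range(200):
        truth = [pf(f"T{i}a", f"T{i}b", method="truth") for i in range(int(rng.integers(1, 5)))]
        preds = [pf(f"T{i}a", f"T{i}b") for i in range(int(rng.integers(0, 5)))] + [
            pf(f"F{j}", f"F{j}x") for j in range(int(rng.integers(0, 4)))
        ]
        s = score_predictions(preds, truth)
        assert 0.0 <= s.precision <= 1.0 and 0.0 <= s.recall <= 1.0 and 0.0 <= s.f1 <= 1.0
        assert s.f1 <= 2 * min(s.precision, s.recall) + 1e-12
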