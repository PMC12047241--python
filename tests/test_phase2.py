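"""Phase-2 quantification: snapping, classification, tallies, filters, report."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lrfusion.annotation import SimilarityMap
from lrfusion.config import FusionCallingConfig
from lrfusion.fusion_contig import build_fusion_contig
from lrfusion.phase2 import (
    SPLICE_CONSENSUS,
    SPLICE_NON_CONSENSUS,
    BreakpointEvidence,
    ContigAlignment,
    apply_final_filters,
    build_report_rows,
    classify_fusion_read,
    classify_splice,
    read_fusion_report,
    snap_alignment_ends,
    tally_breakpoints,
    write_fusion_report,
)


@pytest.fixture(scope="module")
def contig(mini_gms, mini_genome):
    return build_fusion_contig("GA", "GB", mini_gms, mini_genome)


# ---------------------------------------------------------------------------
# snapping


@pytest.mark.parametrize(
    "end,expected",
    [(102, 100), (98, 100), (104, 104), (100, 100), (97, 100)],
)
def test_snap_examples(end, expected):
    aln = ContigAlignment("r", [(10, end, 0, end - 10)])
    snapped = snap_alignment_ends(aln, [100], snap_dist=3)
    assert snapped.blocks[0][1] == expected


def test_snap_never_collapses_blocks():
    aln = ContigAlignment("r", [(99, 102, 0, 3)])
    snapped = snap_alignment_ends(aln, [100], snap_dist=3)
    cs, ce, _, _ = snapped.blocks[0]
    assert cs < ce


@given(
    blocks=st.lists(
        st.tuples(st.integers(0, 500), st.integers(5, 50)).map(lambda t: (t[0], t[0] + t[1])),
        min_size=1,
        max_size=5,
    ),
    boundaries=st.lists(st.integers(0, 600), min_size=1, max_size=10),
)
def test_snap_is_idempotent(blocks, boundaries):
    aln = ContigAlignment("r", [(s, e, 0, e - s) for s, e in blocks])
    once = snap_alignment_ends(aln, boundaries)
    twice = snap_alignment_ends(once, boundaries)
    assert once.blocks == twice.blocks


# ---------------------------------------------------------------------------
# fusion read classification


def _aln_spanning(contig, bp5_override=None, g5_len=None, g3_len=None):
    """Alignment ending at the GA/GB junction with given exonic lengths."""
    g5_end = bp5_override if bp5_override is not None else contig.gene5_end
    g5_len = g5_len if g5_len is not None else 100
    g3_len = g3_len if g3_len is not None else 100
    g3_start = contig.gene3_start
    return ContigAlignment(
        "r",
        [
            (g5_end - g5_len, g5_end, 0, g5_len),
            (g3_start, g3_start + g3_len, g5_len, g5_len + g3_len),
        ],
    )


def test_sufficient_anchors_are_evidence(contig):
    ok, bp = classify_fusion_read(_aln_spanning(contig, g5_len=30, g3_len=30), contig)
    assert ok and bp == (contig.gene5_end, contig.gene3_start)


def test_short_anchor_is_rejected(contig):
    ok, _ = classify_fusion_read(_aln_spanning(contig, g5_len=20, g3_len=150), contig)
    assert not ok


def test_one_sided_alignment_is_rejected(contig):
    aln = ContigAlignment("r", [(0, 200, 0, 200)])
    ok, _ = classify_fusion_read(aln, contig)
    assert not ok


def test_similar_exon_overlap_is_discounted(mini_gms, mini_genome, contig):
    """Evidence confined to an exon flagged similar between the pair fails."""
    smap = SimilarityMap()
    # flag GB's entire first exon as similar to a GA region
    smap.add("GA", "GB", ("t1", 1400, 1600), ("t2", 1000, 1150))
    aln = _aln_spanning(contig, g5_len=40, g3_len=40)
    ok_without, _ = classify_fusion_read(aln, contig, None)
    ok_with, _ = classify_fusion_read(aln, contig, smap)
    assert ok_without and not ok_with


# ---------------------------------------------------------------------------
# splice classification


def test_classify_splice_examples():
    #            0123456789
    seq = "AAAAAGTCCCCAGAAAAA"
    # donor immediately after position 5 is "GT"; acceptor before 13 is "AG"
    donor, acceptor, cls, edge = classify_splice(seq, 5, 13)
    assert (donor, acceptor, cls, edge) == ("GT", "AG", SPLICE_CONSENSUS, False)
    donor, acceptor, cls, _ = classify_splice("AACATTTTTGAA", 2, 10)
    assert cls == SPLICE_NON_CONSENSUS


def test_breakpoint_at_contig_edge_is_flagged():
    *_, cls, edge = classify_splice("ACGT", 3, 1)
    assert cls == SPLICE_NON_CONSENSUS and edge


def test_extended_consensus_set():
    seq = "AAAAAGCCCCCACAAAAA"
    consensus = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})
    donor, acceptor, cls, _ = classify_splice(seq, 5, 13, consensus)
    assert (donor, acceptor) == ("GC", "AC")
    assert cls == SPLICE_NON_CONSENSUS  # GC pairs with AG, not AC


# ---------------------------------------------------------------------------
# tallies


def test_reads_grouped_by_exact_breakpoint(contig):
    bp = (contig.gene5_end, contig.gene3_start)
    evidence = [(f"r{i}", bp) for i in range(5)]
    out = tally_breakpoints(evidence, contig, total_reads=1000)
    assert len(out) == 1 and out[0].read_count == 5
    assert out[0].ffpm == pytest.approx(5000.0)


def test_two_donor_isoforms_tallied_separately(mini_gms, contig):
    ga = mini_gms["GA"]
    donor2 = contig.exon_blocks["GA"][1][1]  # end of GA's second exon
    evidence = [("a", (contig.gene5_end, contig.gene3_start)),
                ("b", (donor2, contig.gene3_start))]
    out = tally_breakpoints(evidence, contig, total_reads=1000)
    assert len(out) == 2


def test_duplicate_read_ids_collapse(contig):
    bp = (contig.gene5_end, contig.gene3_start)
    out = tally_breakpoints([("dup", bp), ("dup", bp)], contig, 1000)
    assert out[0].read_count == 1


def test_simulated_two_isoform_counts(sim_clean):
    """Two planned isoforms of one gene pair tally as separate breakpoints."""
    from lrfusion.pipeline import call_fusions
    from lrfusion.simulate import FusionPlan, SimSpec, simulate

    plans = [
        FusionPlan("GENE01", "GENE06", 0, 1, 7),
        FusionPlan("GENE01", "GENE06", 1, 1, 3),
    ]
    ds = simulate(SimSpec(seed=3, n_genes=10, genes_per_chrom=5, fusions=plans,
                          background_reads_per_gene=5))
    res = call_fusions(ds.gene_models, ds.genome, ds.ideal_segments(), ds.total_reads)
    counts = sorted(r.n_long_reads for r in res.rows)
    assert counts == [3, 7]
    assert all(r.fusion_name == "GENE01--GENE06" for r in res.rows)


# ---------------------------------------------------------------------------
# final filters


def _ev(count, splice=SPLICE_CONSENSUS, ffpm=None, name=("GA", "GB"), bp=(100, 200)):
    return BreakpointEvidence(
        gene5=name[0],
        gene3=name[1],
        contig_break5=bp[0],
        contig_break3=bp[1],
        left_breakpoint="t1:1:+",
        right_breakpoint="t2:1:+",
        donor="GT",
        acceptor="AG",
        splice_class=splice,
        read_ids=[f"{name[0]}{bp[0]}r{i}" for i in range(count)],
        ffpm=ffpm if ffpm is not None else float(count),
    )


def test_nonconsensus_needs_two_reads():
    one = _ev(1, SPLICE_NON_CONSENSUS, ffpm=0.2)
    two = _ev(2, SPLICE_NON_CONSENSUS, ffpm=0.4, bp=(100, 300))
    assert apply_final_filters([one]) == []
    assert apply_final_filters([two]) == [two]


def test_consensus_single_read_kept():
    ev = _ev(1, SPLICE_CONSENSUS, ffpm=0.2)
    assert apply_final_filters([ev]) == [ev]


def test_low_ffpm_breakpoint_dropped():
    ev = _ev(3, ffpm=0.05)
    assert apply_final_filters([ev]) == []


def test_minor_isoform_fraction_rule():
    dominant = _ev(100, bp=(100, 200))
    minor4 = _ev(4, bp=(150, 200))
    minor5 = _ev(5, bp=(180, 200))
    out = apply_final_filters([dominant, minor4, minor5])
    assert dominant in out and minor5 in out and minor4 not in out


def test_filters_monotone_in_thresholds():
    """Raising any threshold never adds a reported breakpoint."""
    evs = [
        _ev(100, bp=(100, 200)),
        _ev(5, bp=(150, 200)),
        _ev(2, SPLICE_NON_CONSENSUS, bp=(170, 200)),
        _ev(30, ffpm=0.3, bp=(190, 200), name=("GX", "GY")),
    ]
    base_cfg = FusionCallingConfig()
    base = {id(e) for e in apply_final_filters(evs, base_cfg)}
    for cfg in (
        FusionCallingConfig(min_ffpm=1.0),
        FusionCallingConfig(min_reads_nonconsensus=3),
        FusionCallingConfig(isoform_frac=0.10),
        FusionCallingConfig(min_ffpm=5.0, min_reads_nonconsensus=10, isoform_frac=0.5),
    ):
        tightened = {id(e) for e in apply_final_filters(evs, cfg)}
        assert tightened <= base


# ---------------------------------------------------------------------------
# report I/O


def test_empty_report_is_header_only(tmp_path):
    path = tmp_path / "report.tsv"
    write_fusion_report([], path)
    lines = path.read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("#FusionName\t")


def test_report_round_trip(tmp_path):
    evs = [
        _ev(7, bp=(100, 200)),
        _ev(3, bp=(120, 200)),
        _ev(2, bp=(140, 200)),
    ]
    rows = build_report_rows(evs)
    path = tmp_path / "report.tsv"
    write_fusion_report(rows, path)
    df = read_fusion_report(path)
    assert len(df) == 3
    assert set(df["#FusionName"]) == {"GA--GB"}
    assert list(df["NumLongReads"]) == [7, 3, 2]  # descending read support
    assert list(df["LongReadIds"].str.split(",").str.len()) == [7, 3, 2]


def test_report_row_sorting_is_deterministic():
    evs = [_ev(3, bp=(120, 200)), _ev(3, bp=(100, 200), name=("AA", "BB")), _ev(9, bp=(90, 200))]
    rows = build_report_rows(evs)
    assert [r.n_long_reads for r in rows] == [9, 3, 3]
    assert rows[1].fusion_name == "AA--BB"  # ties break by name


def test_evidence_counts_bounded_by_candidate_reads(sim_clean):
    from lrfusion.annotation import ExonBoundaryIndex
    from lrfusion.pipeline import call_fusions

    res = call_fusions(sim_clean.gene_models, sim_clean.genome,
                       sim_clean.ideal_segments(), sim_clean.total_reads)
    by_pair = {(c.gene5, c.gene3): c.read_count for c in res.candidates}
    per_fusion: dict[str, int] = {}
    for r in res.rows:
        per_fusion[r.fusion_name] = per_fusion.get(r.fusion_name, 0) + r.n_long_reads
    for name, total in per_fusion.items():
        g5, g3 = name.split("--")
        assert total <= by_pair[(g5, g3)]
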