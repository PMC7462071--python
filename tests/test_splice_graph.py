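"""Splicing graph construction: junction tally, exon segmentation, weights."""

import networkx as nx
import numpy as np

from isoweave.splice_graph import (
    ADJACENCY,
    JUNCTION,
    build_locus_graph,
    build_splicing_graph,
    collect_junctions,
    segment_exons,
)

from conftest import frag, locus_of


def spliced(intron, flank=50, name="r"):
    d, a = intron
    return frag([(d - flank, d), (a, a + flank)], name=name)


def test_collect_junctions_counts_and_threshold():
    mates = [spliced((1050, 1150), name=f"r{i}") for i in range(3)]
    mates.append(spliced((2000, 2100), name="lone"))
    locus = locus_of(mates)
    assert collect_junctions(locus, 2) == {(1050, 1150): 3}
    assert collect_junctions(locus, 1) == {(1050, 1150): 3, (2000, 2100): 1}


def test_collect_junctions_matches_brute_force_tally(rng):
    donors = [1000, 2000, 3000]
    mates = []
    expected = {}
    for i in range(50):
        d = int(donors[rng.integers(0, 3)])
        a = d + int(rng.integers(1, 4)) * 100
        mates.append(spliced((d, a), name=f"r{i}"))
        expected[(d, a)] = expected.get((d, a), 0) + 1
    got = collect_junctions(locus_of(mates), 1)
    assert got == expected


def test_segment_exons_cuts_at_junctions():
    # reads spell intron (100, 200); interior uncovered
    mates = [frag([(0, 100), (200, 300)], name=f"r{i}") for i in range(3)]
    locus = locus_of(mates)
    junctions = collect_junctions(locus, 1)
    assert segment_exons(locus, junctions) == [(0, 100), (200, 300)]


def test_segment_exons_keeps_retained_intron():
    mates = [frag([(0, 100), (200, 300)], name=f"r{i}") for i in range(3)]
    mates += [frag([(120, 180)], name=f"in{i}") for i in range(5)]
    locus = locus_of(mates)
    segs = segment_exons(locus, collect_junctions(locus, 1))
    # the covered stretch inside the intron survives as its own segment
    assert segs == [(0, 100), (120, 180), (200, 300)]


def test_segment_exons_splits_at_coverage_gap():
    mates = [frag([(0, 150)], name="a"), frag([(160, 300)], name="b")]
    locus = locus_of(mates)
    assert segment_exons(locus, {}) == [(0, 150), (160, 300)]


def test_segment_exons_matches_coverage_scan_oracle(rng):
    for _ in range(20):
        mates = []
        for i in range(int(rng.integers(3, 15))):
            s = int(rng.integers(0, 800))
            mates.append(frag([(s, s + int(rng.integers(20, 120)))], name=f"r{i}"))
        junctions = {}
        for _ in range(int(rng.integers(0, 3))):
            d = int(rng.integers(50, 700))
            junctions[(d, d + int(rng.integers(50, 200)))] = 1
        locus = locus_of(mates)
        segs = segment_exons(locus, junctions)
        # oracle: per-base scan
        lo, hi = locus.span
        cov = np.zeros(hi - lo)
        for m in mates:
            for s, e in m.blocks:
                cov[s - lo:e - lo] += 1
        cuts = {c for j in junctions for c in j if lo < c < hi}
        expected = []
        start = None
        for pos in range(lo, hi + 1):
            covered = pos < hi and cov[pos - lo] > 0
            boundary = pos in cuts
            if covered and (start is None):
                start = pos
            elif start is not None and (not covered):
                expected.append((start, pos))
                start = None
            elif start is not None and boundary:
                expected.append((start, pos))
                start = pos
        assert segs == expected


def test_two_exon_graph_weights():
    mates = [spliced((1050, 1150), name=f"r{i}") for i in range(3)]
    locus = locus_of(mates)
    graph = build_locus_graph(locus)
    assert graph.nodes == [(1000, 1050), (1150, 1200)]
    edges = list(graph.g.edges(data=True))
    assert len(edges) == 1
    u, v, d = edges[0]
    assert d["kind"] == JUNCTION and d["weight"] == 3 and d["intron"] == (1050, 1150)


def test_exon_skipping_diamond_motif():
    # exons A, B, C with introns A->B, B->C and A->C
    mates = (
        [frag([(950, 1000), (1200, 1250)], name=f"ab{i}") for i in range(2)]
        + [frag([(1250, 1300), (1500, 1550)], name=f"bc{i}") for i in range(2)]
        + [frag([(950, 1000), (1500, 1550)], name=f"ac{i}") for i in range(2)]
    )
    graph = build_locus_graph(locus_of(mates))
    assert len(graph.nodes) == 3
    kinds = [d["kind"] for _, _, d in graph.g.edges(data=True)]
    assert kinds.count(JUNCTION) == 3


def test_adjacency_edge_weight_counts_crossing_reads():
    # junction cuts at 200 create abutting segments (100,200)+(200,300)
    mates = [frag([(50, 100), (200, 320)], name=f"j{i}") for i in range(2)]
    mates += [frag([(150, 250)], name=f"c{i}") for i in range(4)]
    graph = build_locus_graph(locus_of(mates))
    adj = [(u, v, d) for u, v, d in graph.g.edges(data=True)
           if d["kind"] == ADJACENCY]
    assert len(adj) == 1
    assert adj[0][2]["weight"] == 4  # the 4 crossing unspliced reads


def test_edge_weights_equal_brute_force_recount(rng):
    for _ in range(15):
        mates = []
        introns = [(1100, 1400), (1500, 1900), (1100, 1900)]
        for i in range(int(rng.integers(5, 30))):
            intron = introns[int(rng.integers(0, 3))]
            mates.append(spliced(intron, flank=int(rng.integers(20, 80)),
                                 name=f"r{i}"))
        locus = locus_of(mates)
        graph = build_locus_graph(locus)
        assert nx.is_directed_acyclic_graph(graph.g)
        for u, v, d in graph.junction_edges():
            recount = sum(
                1 for m in mates if d["intron"] in m.introns()
            )
            assert d["weight"] == recount
        # conservation: total junction weight = surviving incidences
        total = sum(d["weight"] for _, _, d in graph.junction_edges())
        assert total == sum(len(m.introns()) for m in mates)


def test_dropped_junction_without_matching_boundary(caplog):
    mates = [frag([(0, 300)], name=f"r{i}") for i in range(3)]
    locus = locus_of(mates)
    # fabricated junction whose boundaries match no segment edge
    graph = build_splicing_graph(locus, {(100, 200): 5}, [(0, 300)])
    assert graph.g.number_of_edges() == 0


def test_topological_order_is_coordinate_order(rng):
    for _ in range(10):
        mates = [spliced((1000 + 500 * k, 1200 + 500 * k), name=f"r{k}{i}")
                 for k in range(int(rng.integers(1, 5))) for i in range(2)]
        graph = build_locus_graph(locus_of(mates))
        for u, v in graph.g.edges:
            assert graph.nodes[u][0] < graph.nodes[v][0]
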