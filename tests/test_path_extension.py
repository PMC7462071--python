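"""Seeded path extension: seed choice, the extension hierarchy, commits,
the cover guarantee, and GTF emission."""

import pytest

from isoweave.line_graph import weight_line_graph
from isoweave.paired_subpaths import (
    ASSEMBLY_DERIVED,
    READ_DERIVED,
    ReliableSubpathSet,
    ScoredPath,
)
from isoweave.path_extension import (
    assemble_graph,
    commit_path,
    extend_left,
    extend_right,
    paths_to_gtf,
    select_seed,
)

from conftest import make_graph, random_graph, random_reliable_set


def rel_of(entries, provenance=READ_DERIVED):
    out = ReliableSubpathSet(provenance=provenance)
    for item in entries:
        nodes, score = item[0], item[1]
        prov = item[2] if len(item) > 2 else provenance
        out.by_length.setdefault(len(nodes), []).append(
            ScoredPath(tuple(nodes), float(score), prov)
        )
    for k in out.by_length:
        out.by_length[k].sort(key=lambda e: (-e.score, e.nodes))
    return out


DIAMOND = make_graph(
    [(0, 100), (200, 300), (400, 500), (600, 700)],
    [(0, 1, 5), (0, 2, 5), (1, 3, 5), (2, 3, 5)],
)
LINEAR = make_graph(
    [(0, 100), (200, 300), (400, 500), (600, 700)],
    [(0, 1, 7), (1, 2, 3), (2, 3, 9)],
)


def project(entries, graph):
    from isoweave.line_graph import project_reliable_set

    return project_reliable_set(entries, graph)


def test_select_seed_longest_first_then_fallback_node():
    line = weight_line_graph(LINEAR, rel_of([]))
    rel_l = project(
        rel_of([((0, 1, 2, 3), 4), ((1, 2, 3), 9)]), LINEAR
    )
    seed = select_seed(rel_l, [], line)
    assert seed == ((0, 1), (1, 2), (2, 3))  # the length-4 G-subpath
    # once covered, fall back to the heaviest unused L-node
    seed2 = select_seed(rel_l, [seed], line)
    assert seed2 is None or seed2 == seed  # everything covered by seed
    partial = (((0, 1),),)
    line2 = weight_line_graph(LINEAR, rel_of([]))
    empty = ReliableSubpathSet()
    assert select_seed(empty, list(partial), line2) == ((2, 3),)  # weight 9


def test_select_seed_prefers_assembly_at_equal_length():
    line = weight_line_graph(DIAMOND, rel_of([]))
    rel_l = project(
        rel_of([((0, 1, 3), 99, READ_DERIVED), ((0, 2, 3), 2, ASSEMBLY_DERIVED)]),
        DIAMOND,
    )
    assert select_seed(rel_l, [], line) == ((0, 2), (2, 3))


def test_extend_right_single_weight1_successor():
    line = weight_line_graph(LINEAR, rel_of([]))
    got = extend_right(((0, 1),), line, {})
    assert got == ((0, 1), (1, 2), (2, 3))


def test_extend_right_witnessed_neighbor_wins():
    rel = rel_of([((0, 1, 3), 2)])
    line = weight_line_graph(DIAMOND, rel)
    rel_l = project(rel, DIAMOND)
    got = extend_right(((0, 1),), line, rel_l.membership())
    assert got == ((0, 1), (1, 3))


def test_extend_right_longer_witness_breaks_tie():
    # both successors witnessed at length 2; only one at length 3
    g = make_graph(
        [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)],
        [(0, 1, 5), (1, 2, 5), (2, 3, 5), (2, 4, 5)],
    )
    rel = rel_of([((1, 2, 3), 3), ((2, 4), 3), ((2, 3), 3)])
    line = weight_line_graph(g, rel)
    rel_l = project(rel, g)
    got = extend_right(((0, 1), (1, 2)), line, rel_l.membership())
    assert got[2] == (2, 3)  # the length-3 witness wins over weight ties


def test_extend_left_mirrors_right():
    rel = rel_of([((0, 2, 3), 2)])
    line = weight_line_graph(DIAMOND, rel)
    rel_l = project(rel, DIAMOND)
    got = extend_left(((2, 3),), line, rel_l.membership())
    assert got == ((0, 2), (2, 3))


def test_extension_choice_matches_hierarchy_oracle(rng):
    """Replaying the rule order (weight-1 edges, then 2-subpath witness,
    then longer witnesses, then max weight, then lexicographic) on every
    branching decision must reproduce extend_right's choice."""
    for _ in range(100):
        g = random_graph(rng)
        rel = random_reliable_set(rng, g)
        line = weight_line_graph(g, rel)
        rel_l = project(rel, g)
        membership = rel_l.membership()
        start = sorted(line.l.nodes)[int(rng.integers(0, line.l.number_of_nodes()))]
        path = (start,)
        while True:
            got = extend_right(path, line, membership)
            if len(got) == len(path):
                break
            # oracle: independent replay of the hierarchy for ONE step
            last = path[-1]
            succs = sorted(line.l.successors(last))
            cands = [s for s in succs if line.edge_weight(last, s) >= 1.0] or succs
            k = 2
            while len(cands) > 1 and k - 1 <= len(path):
                table = membership.get(k, {})
                witnessed = [
                    c for c in cands if path[len(path) - (k - 1):] + (c,) in table
                ]
                if not witnessed:
                    break
                cands = witnessed
                k += 1
            expect = max(cands, key=lambda n: (line.weight(n), [-x for x in n]))
            assert got[len(path)] == expect
            path = path + (expect,)


def test_commit_subtracts_cmin():
    line = weight_line_graph(LINEAR, rel_of([]))
    path = ((0, 1), (1, 2), (2, 3))  # weights 7, 3, 9
    t, c_min = commit_path(path, line)
    assert c_min == 3
    assert [line.weight(n) for n in path] == [4, 0, 6]
    # second commit over shared nodes uses the updated weights
    t2, c2 = commit_path(path, line)
    assert c2 == 0
    assert [line.weight(n) for n in path] == [4, 0, 6]
    assert t2.c_min == 0  # the path is still recorded


def test_assemble_linear_graph_single_path():
    line = weight_line_graph(LINEAR, rel_of([]))
    paths = assemble_graph(line, rel_of([]))
    assert len(paths) == 1
    assert paths[0].g_nodes == (0, 1, 2, 3)
    assert paths[0].c_min == 3


def test_assemble_diamond_recovers_both_isoforms():
    rel = rel_of([((0, 1, 3), 4), ((0, 2, 3), 3)])
    line = weight_line_graph(DIAMOND, rel)
    paths = assemble_graph(line, rel)
    assert {t.g_nodes for t in paths} == {(0, 1, 3), (0, 2, 3)}


def test_assemble_emits_mono_exon_for_isolated_node():
    g = make_graph([(0, 500)], [], mean_cov=[12.5])
    line = weight_line_graph(g, rel_of([]))
    (t,) = assemble_graph(line, rel_of([]))
    assert t.g_nodes == (0,) and t.c_min == 12.5 and t.exon_chain == ((0, 500),)


def test_assemble_cover_and_weight_monotonicity(rng):
    """Every reliable subpath and every L-node ends up covered; node
    weights never increase and never go negative across commits."""
    for _ in range(60):
        g = random_graph(rng)
        rel = random_reliable_set(rng, g, n_paths=int(rng.integers(1, 4)))
        line = weight_line_graph(g, rel)
        before = dict(line.node_weight)
        paths = assemble_graph(line, rel)
        predicted = [t.l_nodes for t in paths if t.l_nodes]
        # cover: reliable subpaths
        from isoweave.line_graph import project_reliable_set

        rel_l = project_reliable_set(rel, g)
        for k, entries in rel_l.by_length.items():
            for e in entries:
                assert any(
                    e.nodes == p[i:i + k]
                    for p in predicted
                    for i in range(len(p) - k + 1)
                ), f"uncovered reliable subpath {e.nodes}"
        # cover: L-nodes
        used = {n for p in predicted for n in p}
        assert used == set(line.l.nodes)
        # weights non-increasing and non-negative
        for n, w in line.node_weight.items():
            assert -1e-9 <= w <= before[n] + 1e-9
        # maximality: emitted paths end at graph sources/sinks
        for t in paths:
            if t.l_nodes:
                assert line.l.out_degree(t.l_nodes[-1]) == 0
                assert line.l.in_degree(t.l_nodes[0]) == 0


def test_paths_to_gtf_filter_and_abutting_merge():
    g = make_graph(
        [(100, 200), (200, 350), (500, 600)],
        [(0, 1, 4), (1, 2, 4)],
    )
    rel = rel_of([])
    line = weight_line_graph(g, rel)
    paths = assemble_graph(line, rel)
    (t,) = paths
    assert t.exon_chain == ((100, 350), (500, 600))  # abutting merged
    lines = paths_to_gtf(paths, g, min_cov=1.5)
    exon_lines = [l for l in lines if "\texon\t" in l]
    coords = [(int(l.split("\t")[3]), int(l.split("\t")[4])) for l in exon_lines]
    assert coords == [(101, 350), (501, 600)]  # 1-based inclusive
    # below min_cov everything is dropped
    assert paths_to_gtf(paths, g, min_cov=100.0) == []


def test_gtf_intron_chain_round_trip(rng):
    for _ in range(20):
        g = random_graph(rng)
        rel = random_reliable_set(rng, g)
        line = weight_line_graph(g, rel)
        paths = assemble_graph(line, rel)
        for t in paths:
            introns = [
                (g.nodes[u][1], g.nodes[v][0])
                for u, v in zip(t.g_nodes, t.g_nodes[1:])
                if g.nodes[u][1] != g.nodes[v][0]
            ]
            assert list(t.intron_chain()) == introns
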