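"""Shared test helpers: hand-built loci/graphs and random fixture factories."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from isoweave.alignment import AlignedFragment, Locus
from isoweave.paired_subpaths import (
    READ_DERIVED,
    ReliableSubpathSet,
    ScoredPath,
)
from isoweave.splice_graph import ADJACENCY, JUNCTION, SplicingGraph


def frag(blocks, name="r", strand="+", mapq=60, first=True):
    return AlignedFragment(
        query_name=name,
        chrom="chrT",
        strand=strand,
        blocks=[tuple(b) for b in blocks],
        mapq=mapq,
        is_first_mate=first,
    )


def locus_of(mates, strand="+"):
    """A Locus holding the given mates as singleton 'pairs'."""
    start = min(m.start for m in mates)
    end = max(m.end for m in mates)
    return Locus("chrT", strand, (start, end), [(m, None) for m in mates])


def make_graph(nodes, edges, mean_cov=None, strand="+", graph_id=0):
    """Build a SplicingGraph directly from interval nodes and edge specs.

    ``edges`` entries: (u, v, weight) -> kind inferred (adjacency when the
    intervals abut, junction otherwise).
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(len(nodes)))
    for u, v, w in edges:
        if nodes[u][1] == nodes[v][0]:
            g.add_edge(u, v, weight=float(w), kind=ADJACENCY)
        else:
            g.add_edge(u, v, weight=float(w), kind=JUNCTION,
                       intron=(nodes[u][1], nodes[v][0]))
    span = (min(s for s, _ in nodes), max(e for _, e in nodes))
    return SplicingGraph(
        chrom="chrT", strand=strand, span=span, nodes=list(nodes), g=g,
        node_mean_cov=list(mean_cov or [10.0] * len(nodes)),
        graph_id=graph_id,
    )


def random_graph(rng, n_min=4, n_max=10, p_edge=0.45):
    """Random coordinate-ordered DAG with positive integer edge weights."""
    n = int(rng.integers(n_min, n_max + 1))
    nodes = [(1000 * i, 1000 * i + 500) for i in range(n)]
    edges = []
    for i in range(n - 1):
        # guarantee connectivity along the backbone
        edges.append((i, i + 1, int(rng.integers(1, 20))))
    for i in range(n):
        for j in range(i + 2, n):
            if rng.random() < p_edge / (j - i):
                edges.append((i, j, int(rng.integers(1, 20))))
    return make_graph(nodes, edges)


def random_reliable_set(rng, graph, n_paths=3):
    """Reliable subpaths derived from random walks through the graph."""
    paths = []
    for _ in range(n_paths):
        sources = [v for v in graph.g.nodes if graph.g.in_degree(v) == 0]
        node = int(sources[rng.integers(0, len(sources))])
        path = [node]
        while True:
            succ = sorted(graph.g.successors(path[-1]))
            if not succ:
                break
            path.append(int(succ[rng.integers(0, len(succ))]))
        paths.append(tuple(path))
    rset = ReliableSubpathSet(provenance=READ_DERIVED)
    windows = {}
    for p in paths:
        for k in range(2, len(p) + 1):
            for i in range(len(p) - k + 1):
                windows.setdefault(k, {}).setdefault(p[i:i + k], 0)
                windows[k][p[i:i + k]] += int(rng.integers(1, 5))
    for k, bucket in windows.items():
        entries = [
            ScoredPath(w, float(c), READ_DERIVED) for w, c in bucket.items()
        ]
        entries.sort(key=lambda e: (-e.score, e.nodes))
        rset.by_length[k] = entries
    return rset


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
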