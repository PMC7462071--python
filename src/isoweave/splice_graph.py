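"""Per-locus weighted splicing graphs.

Nodes are exon segments (maximal covered runs of the locus cut at every
junction boundary); edges are splice junctions (intron-spanning) or
adjacencies between abutting segments.  Edge weights count the fragments
spanning the edge, so sequencing depth is carried directly on the graph.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .alignment import Locus

log = logging.getLogger(__name__)

JUNCTION = "junction"
ADJACENCY = "adjacency"


@dataclass
class SplicingGraph:
    """Weighted DAG over the exon segments of one locus.

    ``nodes`` are coordinate-sorted genomic intervals; node index order is
    a topological order.  The backing ``nx.DiGraph`` holds integer node
    indices with edge attributes ``weight``, ``kind`` and (for junctions)
    ``intron``.
    """

    chrom: str
    strand: str
    span: tuple[int, int]
    nodes: list[tuple[int, int]]
    g: nx.DiGraph
    node_mean_cov: list[float] = field(default_factory=list)
    graph_id: int = 0

    def junction_edges(self) -> list[tuple[int, int, dict]]:
        return [
            (u, v, d) for u, v, d in self.g.edges(data=True) if d["kind"] == JUNCTION
        ]

    def edge_kind(self, u: int, v: int) -> str:
        return self.g.edges[u, v]["kind"]

    def edge_weight(self, u: int, v: int) -> float:
        return self.g.edges[u, v]["weight"]

    def has_adjacency(self, u: int, v: int) -> bool:
        return self.g.has_edge(u, v) and self.g.edges[u, v]["kind"] == ADJACENCY

    def junction_lookup(self) -> dict[tuple[int, int], tuple[int, int]]:
        """intron interval -> (u, v) for every junction edge."""
        return {d["intron"]: (u, v) for u, v, d in self.junction_edges()}

    def node_at_start(self, coord: int) -> int | None:
        i = bisect_right([s for s, _ in self.nodes], coord) - 1
        if 0 <= i < len(self.nodes) and self.nodes[i][0] == coord:
            return i
        return None

    def node_at_end(self, coord: int) -> int | None:
        for i, (_, e) in enumerate(self.nodes):
            if e == coord:
                return i
        return None

    def to_bed(self) -> str:
        """Debug dump: exon segments then junctions, BED6-ish."""
        lines = [
            f"{self.chrom}\t{s}\t{e}\tsegment_{i}\t0\t{self.strand}"
            for i, (s, e) in enumerate(self.nodes)
        ]
        for u, v, d in self.junction_edges():
            s, e = d["intron"]
            lines.append(
                f"{self.chrom}\t{s}\t{e}\tjunction_{u}_{v}\t{int(d['weight'])}\t{self.strand}"
            )
        return "\n".join(lines) + "\n"


def collect_junctions(
    locus: Locus, min_junction_reads: int = 1
) -> dict[tuple[int, int], int]:
    """Tally candidate introns from block gaps of every mate in the locus.

    Each gap between consecutive blocks of any mate is a candidate intron;
    candidates supported by fewer than ``min_junction_reads`` mates are
    discarded.
    """
    counts: dict[tuple[int, int], int] = {}
    for mate in locus.mates():
        for intron in mate.introns():
            counts[intron] = counts.get(intron, 0) + 1
    return {k: c for k, c in counts.items() if c >= min_junction_reads}


def _coverage_array(locus: Locus) -> np.ndarray:
    start, end = locus.span
    cov = np.zeros(end - start, dtype=np.int64)
    for mate in locus.mates():
        for bs, be in mate.blocks:
            cov[bs - start : be - start] += 1
    return cov


def segment_exons(
    locus: Locus, junctions: dict[tuple[int, int], int]
) -> list[tuple[int, int]]:
    """Cut the locus at every junction boundary; keep covered runs.

    Maximal runs of base-level coverage > 0 between cut points become exon
    segments.  A retained intron (reads lying inside it) therefore stays in
    the graph as a covered segment; uncovered intron interiors vanish.
    """
    start, end = locus.span
    cov = _coverage_array(locus)
    cuts = sorted(
        {c for intron in junctions for c in intron if start < c < end}
        | {start, end}
    )
    segments: list[tuple[int, int]] = []
    for left, right in zip(cuts, cuts[1:]):
        window = cov[left - start : right - start]
        covered = window > 0
        if not covered.any():
            continue
        # maximal covered runs within the window
        edges = np.flatnonzero(np.diff(covered.astype(np.int8)))
        bounds = np.concatenate([[0] if covered[0] else [], edges + 1,
                                 [len(window)] if covered[-1] else []]).astype(int)
        runs = bounds.reshape(-1, 2) if len(bounds) % 2 == 0 else []
        for a, b in runs:
            segments.append((left + int(a), left + int(b)))
    segments.sort()
    return segments


def build_splicing_graph(
    locus: Locus,
    junctions: dict[tuple[int, int], int],
    segments: list[tuple[int, int]],
    graph_id: int = 0,
) -> SplicingGraph:
    """Assemble the weighted DAG from segments and junction counts.

    One junction edge per retained intron whose donor and acceptor match
    segment boundaries (weight = junction count); one adjacency edge per
    abutting segment pair crossed by at least one read block (weight =
    crossing count).  Junctions whose boundaries match no segment are
    dropped with a warning.
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(len(segments)))

    end_at = {e: i for i, (s, e) in enumerate(segments)}
    start_at = {s: i for i, (s, e) in enumerate(segments)}

    for intron, count in sorted(junctions.items()):
        donor, acceptor = intron
        u, v = end_at.get(donor), start_at.get(acceptor)
        if u is None or v is None or u >= v:
            log.warning(
                "junction %s:%d-%d matches no segment boundary; dropped",
                locus.chrom, donor, acceptor,
            )
            continue
        g.add_edge(u, v, weight=float(count), kind=JUNCTION, intron=intron)

    # adjacency edges: abutting segments crossed by >= 1 read block
    boundary_cross: dict[int, int] = {}
    for i in range(len(segments) - 1):
        if segments[i][1] == segments[i + 1][0]:
            boundary_cross[segments[i][1]] = 0
    for mate in locus.mates():
        for bs, be in mate.blocks:
            for b in list(boundary_cross):
                if bs < b < be:
                    boundary_cross[b] += 1
    for i in range(len(segments) - 1):
        b = segments[i][1]
        if b in boundary_cross and boundary_cross[b] >= 1:
            g.add_edge(i, i + 1, weight=float(boundary_cross[b]), kind=ADJACENCY)

    cov = _coverage_array(locus)
    start = locus.span[0]
    mean_cov = [
        float(np.mean(cov[s - start : e - start])) if e > s else 0.0
        for s, e in segments
    ]

    assert nx.is_directed_acyclic_graph(g)
    return SplicingGraph(
        chrom=locus.chrom,
        strand=locus.strand,
        span=locus.span,
        nodes=list(segments),
        g=g,
        node_mean_cov=mean_cov,
        graph_id=graph_id,
    )


def build_locus_graph(
    locus: Locus, min_junction_reads: int = 1, graph_id: int = 0
) -> SplicingGraph:
    """Convenience: junctions -> segments -> graph for one locus."""
    junctions = collect_junctions(locus, min_junction_reads)
    segments = segment_exons(locus, junctions)
    return build_splicing_graph(locus, junctions, segments, graph_id=graph_id)
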