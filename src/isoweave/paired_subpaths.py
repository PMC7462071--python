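"""Paired subpaths: phasing evidence from read pairs over a splicing graph.

A read pair whose two mates map to node paths P1 and P2 spells a paired
subpath P = P1 -> connector -> P2 when exactly one connecting path exists
and the result visits at least three nodes.  Paired subpaths are decomposed
into k-node windows; windows whose summed coverage reaches the reliability
threshold (default 2) become reliable subpaths and later seed the assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

from .alignment import AlignedFragment
from .splice_graph import SplicingGraph

log = logging.getLogger(__name__)

# provenance tags
READ_DERIVED = "read"
ASSEMBLY_DERIVED = "assembly"
MERGED = "merged"

#: cap on connector enumeration: hitting it counts as "more than one"
MAX_CONNECTORS = 64
MAX_CONNECTOR_DEPTH = 32


class ScoredPath(NamedTuple):
    """A node path with its evidence score and provenance."""

    nodes: tuple[int, ...]
    score: float
    provenance: str


@dataclass
class PairedSubpath:
    nodes: tuple[int, ...]
    coverage: int


@dataclass
class ReliableSubpathSet:
    """Reliable subpaths clustered by length, sorted by score descending."""

    by_length: dict[int, list[ScoredPath]] = field(default_factory=dict)
    provenance: str = READ_DERIVED

    def lengths(self) -> list[int]:
        return sorted(self.by_length)

    def all_entries(self) -> list[ScoredPath]:
        return [e for k in self.lengths() for e in self.by_length[k]]

    def membership(self) -> dict[int, dict[tuple[int, ...], ScoredPath]]:
        """Per-length O(1) lookup tables (used by the extension rules)."""
        return {
            k: {e.nodes: e for e in entries} for k, entries in self.by_length.items()
        }

    def to_tsv(self, graph_id: int = 0) -> str:
        lines = ["graph_id\tk\tnodes\tscore\tprovenance"]
        for k in self.lengths():
            for e in self.by_length[k]:
                nodes = ",".join(map(str, e.nodes))
                lines.append(f"{graph_id}\t{k}\t{nodes}\t{e.score:g}\t{e.provenance}")
        return "\n".join(lines) + "\n"


def fragment_to_node_path(
    fragment: AlignedFragment, graph: SplicingGraph, tol: int = 0
) -> Optional[tuple[int, ...]]:
    """Map one mate's block chain to a node path of the splicing graph.

    Each block must be tiled by a run of abutting segments (adjacency edges
    between consecutive ones); each block gap must coincide exactly with a
    junction edge.  Any mismatch yields ``None`` ("unmapped" is a value, not
    an error: reads whose junctions were filtered below threshold land here).
    """
    path: list[int] = []
    junction_by_intron = graph.junction_lookup()
    for bi, (bs, be) in enumerate(fragment.blocks):
        run = [
            i
            for i, (s, e) in enumerate(graph.nodes)
            if s < be and bs < e  # overlap
        ]
        if not run:
            return None
        # block must sit inside the union of its run (tolerance at the ends)
        if bs < graph.nodes[run[0]][0] - tol or be > graph.nodes[run[-1]][1] + tol:
            return None
        for a, b in zip(run, run[1:]):
            if graph.nodes[a][1] != graph.nodes[b][0] or not graph.has_adjacency(a, b):
                return None
        if bi > 0:
            intron = (fragment.blocks[bi - 1][1], bs)
            edge = junction_by_intron.get(intron)
            if edge is None or edge != (path[-1], run[0]):
                return None
        path.extend(run)
    return tuple(path)


def _enumerate_connectors(
    graph: SplicingGraph, src: int, dst: int
) -> Optional[list[list[int]]]:
    """All paths src -> dst; ``None`` when the enumeration cap is hit."""
    found: list[list[int]] = []
    stack = [(src, [src])]
    while stack:
        node, p = stack.pop()
        if node == dst:
            found.append(p)
            if len(found) >= MAX_CONNECTORS:
                return None
            continue
        if len(p) >= MAX_CONNECTOR_DEPTH:
            return None
        for nxt in sorted(graph.g.successors(node)):
            if nxt <= dst:
                stack.append((nxt, p + [nxt]))
    return found


def connect_pair(
    p1: tuple[int, ...], p2: tuple[int, ...], graph: SplicingGraph
) -> Optional[PairedSubpath]:
    """Join the two mates' node paths through a unique connecting path.

    If the paths overlap (the right mate starts on or before the left
    mate's last node) they are merged directly when the shared stretch is
    consistent.  Otherwise every connecting path is enumerated; exactly one
    must exist.  Either way the merged path must visit >= 3 nodes (the
    p + s + q >= 3 rule); shorter evidence is indistinguishable from a
    single junction already present in the graph.
    """
    if not p1 or not p2:
        return None
    if p2[0] <= p1[-1]:
        # overlap case: p2 must begin inside p1 and agree on the shared part
        if p2[0] not in p1:
            log.debug("inconsistent mate overlap: %s vs %s", p1, p2)
            return None
        i = p1.index(p2[0])
        shared = min(len(p1) - i, len(p2))
        if p1[i : i + shared] != p2[:shared]:
            log.debug("mates disagree on shared nodes: %s vs %s", p1, p2)
            return None
        merged = p1 + p2[shared:]
    else:
        connectors = _enumerate_connectors(graph, p1[-1], p2[0])
        if connectors is None or len(connectors) != 1:
            return None
        interior = connectors[0][1:-1]
        merged = p1 + tuple(interior) + p2
    if len(merged) < 3:
        return None
    return PairedSubpath(nodes=tuple(merged), coverage=1)


def collect_paired_subpaths(
    pairs: Iterable[tuple[AlignedFragment, Optional[AlignedFragment]]],
    graph: SplicingGraph,
) -> list[PairedSubpath]:
    """Map every pair, connect mates, and aggregate identical subpaths."""
    tally: dict[tuple[int, ...], int] = {}
    for left, right in pairs:
        if right is None:
            continue
        q1 = fragment_to_node_path(left, graph)
        q2 = fragment_to_node_path(right, graph)
        if q1 is None or q2 is None:
            continue
        sub = connect_pair(q1, q2, graph)
        if sub is not None:
            tally[sub.nodes] = tally.get(sub.nodes, 0) + 1
    return [PairedSubpath(nodes=n, coverage=c) for n, c in sorted(tally.items())]


def decompose_reliable(
    subpaths: Iterable[PairedSubpath],
    min_score: int = 2,
    min_k: int = 2,
) -> ReliableSubpathSet:
    """Window decomposition with coverage aggregation and thresholding.

    For every k from ``min_k`` to the longest subpath length, each length-k
    window of each paired subpath is a paired k-subpath whose coverage is
    the sum of the coverages of all subpaths containing it.  Windows with
    coverage >= ``min_score`` are reliable.  Within each length class
    entries are sorted by coverage descending, ties lexicographically.
    """
    window_cov: dict[int, dict[tuple[int, ...], int]] = {}
    for sub in subpaths:
        n = len(sub.nodes)
        for k in range(min_k, n + 1):
            bucket = window_cov.setdefault(k, {})
            for i in range(n - k + 1):
                w = sub.nodes[i : i + k]
                bucket[w] = bucket.get(w, 0) + sub.coverage
    out = ReliableSubpathSet(provenance=READ_DERIVED)
    for k, bucket in window_cov.items():
        entries = [
            ScoredPath(nodes=w, score=float(c), provenance=READ_DERIVED)
            for w, c in bucket.items()
            if c >= min_score
        ]
        entries.sort(key=lambda e: (-e.score, e.nodes))
        if entries:
            out.by_length[k] = entries
    return out
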