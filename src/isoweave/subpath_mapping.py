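"""Anchor reliable assembly subpaths onto splicing graphs and merge evidence.

Assembly subpaths live in colored-graph coordinates (exon intervals from
assembler GTFs); the assembly itself runs on read-derived splicing graphs.
A junction hash index (key: chromosome, strand, donor, acceptor) locates
each assembly subpath's graph; its exons are then translated into runs of
splicing-graph segments joined by adjacency edges.  Finally read-derived
and assembly-derived reliable sets are merged, dropping duplicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .alignment import UNKNOWN
from .colored_graph import ColoredGraph
from .paired_subpaths import (
    ASSEMBLY_DERIVED,
    MERGED,
    ReliableSubpathSet,
    ScoredPath,
)
from .splice_graph import SplicingGraph

log = logging.getLogger(__name__)

JunctionKey = tuple[str, str, int, int]


@dataclass
class JunctionIndex:
    """Hash table from junction coordinates to (graph id, edge)."""

    table: dict[JunctionKey, tuple[int, tuple[int, int]]] = field(
        default_factory=dict
    )

    def lookup(
        self, chrom: str, strand: str, donor: int, acceptor: int
    ) -> Optional[tuple[int, tuple[int, int]]]:
        """Exact lookup, tolerating unknown strand on either side."""
        hit = self.table.get((chrom, strand, donor, acceptor))
        if hit is not None:
            return hit
        if strand == UNKNOWN:
            candidates = [
                self.table[k]
                for s in ("+", "-")
                if (k := (chrom, s, donor, acceptor)) in self.table
            ]
            if len(candidates) == 1:
                return candidates[0]
            if len(candidates) > 1:
                log.warning(
                    "junction %s:%d-%d ambiguous across strands",
                    chrom, donor, acceptor,
                )
            return None
        return self.table.get((chrom, UNKNOWN, donor, acceptor))


def build_junction_index(graphs: list[SplicingGraph]) -> JunctionIndex:
    """One entry per junction edge of every graph; adjacencies not indexed.

    A duplicate key across graphs is an error: loci must not share
    junctions.
    """
    index = JunctionIndex()
    for gi, graph in enumerate(graphs):
        for u, v, data in graph.junction_edges():
            donor, acceptor = data["intron"]
            key = (graph.chrom, graph.strand, donor, acceptor)
            if key in index.table:
                raise ValueError(f"duplicate junction key {key} across graphs")
            index.table[key] = (gi, (u, v))
    return index


def _segment_run(
    graph: SplicingGraph, anchor: int, exon: tuple[int, int], direction: int
) -> list[int]:
    """Extend from ``anchor`` through adjacency edges while staying in exon."""
    run = [anchor]
    while True:
        n = run[-1] + direction
        if not (0 <= n < len(graph.nodes)):
            break
        a, b = (run[-1], n) if direction > 0 else (n, run[-1])
        s, e = graph.nodes[n]
        if not graph.has_adjacency(a, b) or s < exon[0] or e > exon[1]:
            break
        run.append(n)
    return run[::-1] if direction < 0 else run


def map_assembly_subpath(
    exon_path: tuple[tuple[int, int], ...],
    chrom: str,
    strand: str,
    index: JunctionIndex,
    graphs: list[SplicingGraph],
) -> Optional[tuple[int, tuple[int, ...]]]:
    """Locate an assembly subpath (a chain of exon intervals) in a graph.

    Every junction between consecutive exons must hit the index and resolve
    to the same splicing graph, and the induced edge sequence must form a
    connected path there (intra-exon adjacency edges are filled in where a
    colored-graph exon spans several segments).  Returns
    ``(graph_id, node path)`` or ``None`` (unmapped).
    """
    junctions = []
    for (s1, e1), (s2, e2) in zip(exon_path, exon_path[1:]):
        if e1 < s2:
            junctions.append((e1, s2))
        elif e1 != s2:
            return None  # overlapping exons cannot be a transcript chain
    if not junctions:
        return None  # mono-exon subpaths are matched by overlap, not here

    hits = [index.lookup(chrom, strand, d, a) for d, a in junctions]
    if any(h is None for h in hits):
        return None
    gids = {gid for gid, _ in hits}
    if len(gids) != 1:
        log.warning("assembly subpath spans junctions of %d graphs", len(gids))
        return None
    gid = gids.pop()
    graph = graphs[gid]
    edges = [edge for _, edge in hits]

    # first exon: extend left from the first junction's donor segment
    path = _segment_run(graph, edges[0][0], exon_path[0], direction=-1)
    for i, (u, v) in enumerate(edges):
        if path[-1] != u:
            return None
        if i + 1 < len(edges):
            # internal exon: walk adjacency edges from v to the next donor u'
            nxt_u = edges[i + 1][0]
            walk = [v]
            while walk[-1] != nxt_u:
                n = walk[-1] + 1
                if n > nxt_u or not graph.has_adjacency(walk[-1], n):
                    return None
                walk.append(n)
            path.extend(walk)
        else:
            # last exon: extend right within the exon interval
            path.extend(_segment_run(graph, v, exon_path[-1], direction=+1))
    return gid, tuple(path)


def match_mono_exon(
    exon: tuple[int, int],
    chrom: str,
    strand: str,
    graphs: list[SplicingGraph],
    min_reciprocal: float = 0.5,
) -> Optional[tuple[int, int]]:
    """Match a mono-exon transcript to a single-node splicing graph.

    Junction-free transcripts cannot use the index; they match a
    single-node graph when the reciprocal overlap of exon and segment is at
    least ``min_reciprocal`` in both directions.
    """
    best = None
    for gi, graph in enumerate(graphs):
        if len(graph.nodes) != 1 or graph.g.number_of_edges() > 0:
            continue
        if graph.chrom != chrom or not (
            graph.strand == strand or UNKNOWN in (graph.strand, strand)
        ):
            continue
        s, e = graph.nodes[0]
        ov = min(e, exon[1]) - max(s, exon[0])
        if ov <= 0:
            continue
        if ov >= min_reciprocal * (e - s) and ov >= min_reciprocal * (
            exon[1] - exon[0]
        ):
            if best is None or ov > best[1]:
                best = ((gi, 0), ov)
    return best[0] if best else None


def map_reliable_assembly_set(
    assembly: ReliableSubpathSet,
    colored: ColoredGraph,
    index: JunctionIndex,
    graphs: list[SplicingGraph],
) -> dict[int, ReliableSubpathSet]:
    """Map a colored graph's reliable set onto splicing graphs, per graph id.

    Subpaths whose junctions never made it into any splicing graph (unseen
    in the reads) are dropped and counted in the log.
    """
    per_graph: dict[int, dict[int, list[ScoredPath]]] = {}
    dropped = 0
    for k, entries in assembly.by_length.items():
        for entry in entries:
            exon_path = tuple(colored.nodes[i] for i in entry.nodes)
            hit = map_assembly_subpath(
                exon_path, colored.chrom, colored.strand, index, graphs
            )
            if hit is None:
                dropped += 1
                continue
            gid, nodes = hit
            if len(nodes) < 2:
                continue
            per_graph.setdefault(gid, {}).setdefault(len(nodes), []).append(
                ScoredPath(nodes=nodes, score=entry.score, provenance=ASSEMBLY_DERIVED)
            )
    if dropped:
        log.info("%d reliable assembly subpaths unmapped (junctions absent)", dropped)
    out: dict[int, ReliableSubpathSet] = {}
    for gid, by_len in per_graph.items():
        rset = ReliableSubpathSet(provenance=ASSEMBLY_DERIVED)
        for k, entries in by_len.items():
            uniq: dict[tuple[int, ...], ScoredPath] = {}
            for e in entries:
                old = uniq.get(e.nodes)
                if old is None or e.score > old.score:
                    uniq[e.nodes] = e
            rset.by_length[k] = sorted(
                uniq.values(), key=lambda e: (-e.score, e.nodes)
            )
        out[gid] = rset
    return out


def merge_reliable(
    paired: ReliableSubpathSet, assembly: ReliableSubpathSet
) -> ReliableSubpathSet:
    """Union of read-derived and assembly-derived reliable subpaths.

    Coverage (read pairs) and depth (assemblers) are incommensurable, so
    scores are first normalized to rank positions in [0, 1] within each
    length class; a node sequence present in both sets keeps one copy with
    provenance "merged" and the larger normalized score.  Sorting within
    each length class: score descending, assembly/merged before read-only
    at ties, then lexicographic.
    """

    def normalized(rset: ReliableSubpathSet) -> dict[int, list[ScoredPath]]:
        out = {}
        for k, entries in rset.by_length.items():
            n = len(entries)
            out[k] = [
                ScoredPath(e.nodes, 1.0 - i / n, e.provenance)
                for i, e in enumerate(entries)
            ]
        return out

    prov_rank = {ASSEMBLY_DERIVED: 0, MERGED: 0, "read": 1}
    merged = ReliableSubpathSet(provenance=MERGED)
    np_, na_ = normalized(paired), normalized(assembly)
    for k in sorted(set(np_) | set(na_)):
        union: dict[tuple[int, ...], ScoredPath] = {}
        for e in np_.get(k, []):
            union[e.nodes] = e
        for e in na_.get(k, []):
            old = union.get(e.nodes)
            if old is None:
                union[e.nodes] = e
            else:
                union[e.nodes] = ScoredPath(
                    e.nodes, max(old.score, e.score), MERGED
                )
        merged.by_length[k] = sorted(
            union.values(),
            key=lambda e: (-e.score, prov_rank.get(e.provenance, 1), e.nodes),
        )
    return merged
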