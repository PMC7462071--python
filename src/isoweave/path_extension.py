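"""Seeded greedy path extension: the assembly core.

Transcripts are found as a path cover over the weighted line graph.  Each
round seeds the longest reliable subpath not yet covered by a predicted
path (falling back to the heaviest unused L-node), extends it rightward
and leftward under a fixed preference hierarchy, and commits the maximal
path: its minimum node weight c_min is recorded as the transcript's
abundance proxy and subtracted from every on-path node, so the next round
sees what coverage remains.

Extension hierarchy at each step, mirrored for leftward extension:
  1. candidate neighbors reachable through weight-1 L-edges (fallback: all
     neighbors, so no downstream node is stranded; ``strict_binary`` stops
     instead);
  2. among several, keep those whose junction with the current path is
     witnessed by a reliable 2-subpath, then 3-subpath, ... ascending while
     more than one candidate survives and a longer witness exists;
  3. then the largest current node weight;
  4. then the lexicographically smallest node — the tie-break of last
     resort that makes output bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .line_graph import LineGraph, LNode, project_reliable_set
from .paired_subpaths import ASSEMBLY_DERIVED, MERGED, ReliableSubpathSet
from .splice_graph import SplicingGraph

log = logging.getLogger(__name__)

MIN_COV_DEFAULT = 1.5
_PROV_RANK = {ASSEMBLY_DERIVED: 0, MERGED: 0}


@dataclass
class TranscriptPath:
    """A predicted transcript: an edge path in G plus its abundance proxy."""

    l_nodes: tuple[LNode, ...]
    g_nodes: tuple[int, ...]
    c_min: float
    exon_chain: tuple[tuple[int, int], ...]

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exon_chain[i][1], self.exon_chain[i + 1][0])
            for i in range(len(self.exon_chain) - 1)
        )


def _is_subsequence(sub: tuple, path: tuple) -> bool:
    n, m = len(sub), len(path)
    return any(path[i : i + n] == sub for i in range(m - n + 1))


def _merge_abutting(segments: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    exons: list[list[int]] = []
    for s, e in segments:
        if exons and exons[-1][1] == s:
            exons[-1][1] = e
        else:
            exons.append([s, e])
    return tuple((s, e) for s, e in exons)


def _g_path(l_path: tuple[LNode, ...]) -> tuple[int, ...]:
    return (l_path[0][0],) + tuple(e[1] for e in l_path)


def select_seed(
    reliable_l: ReliableSubpathSet,
    predicted: list[tuple[LNode, ...]],
    line: LineGraph,
) -> tuple[LNode, ...] | None:
    """Pick the next seed, or ``None`` when the cover is complete.

    Longest uncovered reliable L-subpath first (ties: assembly-derived
    before read-derived, then higher score, then lexicographic); when all
    are covered, the unused L-node with the largest weight; when every
    node is used, done.
    """
    for k in sorted(reliable_l.by_length, reverse=True):
        best = None
        for e in reliable_l.by_length[k]:
            if any(_is_subsequence(e.nodes, p) for p in predicted):
                continue
            key = (_PROV_RANK.get(e.provenance, 1), -e.score, e.nodes)
            if best is None or key < best[0]:
                best = (key, e.nodes)
        if best is not None:
            return best[1]
    used = {n for p in predicted for n in p}
    unused = [n for n in line.l.nodes if n not in used]
    if not unused:
        return None
    best_node = max(unused, key=lambda n: (line.weight(n), [-c for c in n]))
    return (best_node,)


def _filter_by_witness(
    candidates: list[LNode],
    path: tuple[LNode, ...],
    membership: dict[int, dict],
    rightward: bool,
) -> list[LNode]:
    k = 2
    while len(candidates) > 1:
        if k - 1 > len(path) or k not in membership:
            break
        table = membership[k]
        if rightward:
            suffix = path[len(path) - (k - 1) :]
            witnessed = [c for c in candidates if suffix + (c,) in table]
        else:
            prefix = path[: k - 1]
            witnessed = [c for c in candidates if (c,) + prefix in table]
        if witnessed:
            candidates = witnessed
        k += 1
    return candidates


def _pick(candidates: list[LNode], line: LineGraph) -> LNode:
    return max(candidates, key=lambda n: (line.weight(n), [-c for c in n]))


def extend_right(
    path: tuple[LNode, ...],
    line: LineGraph,
    membership: dict[int, dict],
    strict_binary: bool = False,
) -> tuple[LNode, ...]:
    """Extend rightward until the last node has no outgoing L-edges."""
    while True:
        last = path[-1]
        succs = sorted(line.l.successors(last))
        if not succs:
            return path
        candidates = [s for s in succs if line.edge_weight(last, s) >= 1.0]
        if not candidates:
            if strict_binary:
                return path
            candidates = succs
        if len(candidates) > 1:
            candidates = _filter_by_witness(candidates, path, membership, True)
        path = path + (_pick(candidates, line),)


def extend_left(
    path: tuple[LNode, ...],
    line: LineGraph,
    membership: dict[int, dict],
    strict_binary: bool = False,
) -> tuple[LNode, ...]:
    """Mirror of :func:`extend_right` over predecessors and prefix witnesses."""
    while True:
        first = path[0]
        preds = sorted(line.l.predecessors(first))
        if not preds:
            return path
        candidates = [p for p in preds if line.edge_weight(p, first) >= 1.0]
        if not candidates:
            if strict_binary:
                return path
            candidates = preds
        if len(candidates) > 1:
            candidates = _filter_by_witness(candidates, path, membership, False)
        path = (_pick(candidates, line),) + path


def commit_path(
    path: tuple[LNode, ...], line: LineGraph
) -> tuple[TranscriptPath, float]:
    """Record the path, subtract c_min from every on-path node weight."""
    c_min = min(line.weight(n) for n in path)
    for n in set(path):
        line.set_weight(n, max(0.0, line.weight(n) - c_min))
    g_nodes = _g_path(path)
    exon_chain = _merge_abutting([line.graph.nodes[i] for i in g_nodes])
    return (
        TranscriptPath(
            l_nodes=path, g_nodes=g_nodes, c_min=c_min, exon_chain=exon_chain
        ),
        c_min,
    )


def assemble_graph(
    line: LineGraph,
    reliable: ReliableSubpathSet,
    strict_binary: bool = False,
    max_rounds_factor: int = 10,
) -> list[TranscriptPath]:
    """Seed/extend/commit until every reliable subpath and L-node is covered.

    ``reliable`` is the merged set in splicing-graph coordinates; it is
    projected onto L here.  Isolated G-nodes (mono-exon candidates) are
    emitted as single-exon paths with c_min equal to their mean base
    coverage.
    """
    graph = line.graph
    reliable_l = project_reliable_set(reliable, graph)
    membership = reliable_l.membership()
    predicted: list[tuple[LNode, ...]] = []
    transcripts: list[TranscriptPath] = []

    cap = max(1, max_rounds_factor * max(1, line.l.number_of_nodes()))
    rounds = 0
    while True:
        seed = select_seed(reliable_l, predicted, line)
        if seed is None:
            break
        rounds += 1
        if rounds > cap:
            raise RuntimeError(
                f"path extension failed to terminate after {cap} rounds "
                f"(graph {graph.graph_id}: {line.l.number_of_nodes()} L-nodes, "
                f"{len(predicted)} paths committed)"
            )
        path = extend_right(seed, line, membership, strict_binary)
        path = extend_left(path, line, membership, strict_binary)
        t, _ = commit_path(path, line)
        predicted.append(path)
        transcripts.append(t)

    # isolated G-nodes never appear in L: emit them as mono-exon transcripts
    for i in graph.g.nodes:
        if graph.g.degree(i) == 0:
            transcripts.append(
                TranscriptPath(
                    l_nodes=(),
                    g_nodes=(i,),
                    c_min=float(graph.node_mean_cov[i]),
                    exon_chain=(graph.nodes[i],),
                )
            )
    return transcripts


def paths_to_gtf(
    paths: list[TranscriptPath],
    graph: SplicingGraph,
    min_cov: float = MIN_COV_DEFAULT,
    gene_id: str | None = None,
    source: str = "isoweave",
) -> list[str]:
    """Emit transcript + exon GTF lines (1-based inclusive coordinates).

    Paths with c_min below ``min_cov`` are dropped — the post-assembly
    expression filter trading precision against sensitivity.
    """
    gene = gene_id or f"ISOW.{graph.graph_id + 1}"
    strand = graph.strand if graph.strand in "+-" else "."
    lines: list[str] = []
    kept = 0
    for t in sorted(paths, key=lambda t: (t.exon_chain, -t.c_min)):
        if t.c_min < min_cov:
            continue
        kept += 1
        tid = f"{gene}.{kept}"
        start = t.exon_chain[0][0] + 1
        end = t.exon_chain[-1][1]
        attrs = f'gene_id "{gene}"; transcript_id "{tid}"; cov "{t.c_min:.3f}";'
        lines.append(
            f"{graph.chrom}\t{source}\ttranscript\t{start}\t{end}\t"
            f"{t.c_min:.3f}\t{strand}\t.\t{attrs}"
        )
        for i, (s, e) in enumerate(t.exon_chain, start=1):
            lines.append(
                f"{graph.chrom}\t{source}\texon\t{s + 1}\t{e}\t"
                f"{t.c_min:.3f}\t{strand}\t.\t{attrs} exon_number \"{i}\";"
            )
    return lines
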